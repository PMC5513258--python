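"""Synthetic RAD read-count piles with known genotypes and collapsed paralogs.

The generator emulates the study design the pipeline is built for: 100-bp RAD
loci sequenced across a small panel of diploid individuals.  Segregating sites
arise with per-site probability ``theta_sim``; the derived-allele count among
the ``2 n`` sampled gene copies is drawn from the neutral folded site-frequency
spectrum (probability proportional to ``1/i``), and individual genotypes then
follow Hardy-Weinberg proportions at that frequency.

A fraction of loci are "collapsed paralogs": the reference locus hides
``copy_number - 1`` additional diverged genomic copies, fixed in every
individual.  Divergence sites (per-site probability ``paralog_divergence``)
carry a fixed alternate base on every duplicate copy, so the pooled pile looks
heterozygous in every individual while the truth genotypes within each copy
stay homozygous -- the classic heterozygote-excess / MAF-0.5 / negative-FIS
signature, together with proportionally elevated coverage.

Per-site, per-individual read depth is Poisson with mean
``coverage_mean * copy_number`` (``* 1`` for single-copy loci); reads pick one
of the ``2 * copy_number`` gene copies uniformly and are mis-read to one of the
three other bases uniformly with probability ``error_rate``.  Reads are
independent across sites (no read-level linkage: the downstream model is
strictly per-site).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import Locus, PileSet
from .likelihood import BASES


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic pile generator (defaults match the study design)."""

    n_individuals: int = 9
    n_loci: int = 500
    locus_length: int = 100
    theta_sim: float = 0.01
    paralog_fraction: float = 0.2
    paralog_divergence: float = 0.02
    copy_number: int = 3
    coverage_mean: float = 8.0
    error_rate: float = 0.005
    assay_fail_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.n_individuals >= 2, "n_individuals must be >= 2"),
            (self.n_loci >= 1, "n_loci must be >= 1"),
            (self.locus_length >= 1, "locus_length must be >= 1"),
            (0.0 <= self.theta_sim <= 0.1, "theta_sim must lie in [0, 0.1]"),
            (0.0 <= self.paralog_fraction <= 1.0, "paralog_fraction must lie in [0, 1]"),
            (0.0 <= self.paralog_divergence <= 1.0, "paralog_divergence must lie in [0, 1]"),
            (self.copy_number >= 2, "copy_number must be >= 2"),
            (self.coverage_mean > 0, "coverage_mean must be > 0"),
            (0.0 <= self.error_rate <= 0.25, "error_rate must lie in [0, 0.25]"),
            (0.0 <= self.assay_fail_rate <= 1.0, "assay_fail_rate must lie in [0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(msg)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``genotypes``: one row per (locus, segregating site, individual) with the
    true unordered genotype on the reference copy.  ``paralogs``: one row per
    locus with paralogy status, copy number and fixed-difference sites.
    """

    genotypes: pd.DataFrame
    paralogs: pd.DataFrame
    config: SimConfig
    individuals: list[str] = field(default_factory=list)

    def snp_ids(self) -> list[str]:
        if self.genotypes.empty:
            return []
        keys = self.genotypes[["locus_id", "pos"]].drop_duplicates()
        return [f"{l}:{p}" for l, p in keys.itertuples(index=False)]

    def genotype_matrix(self) -> pd.DataFrame:
        """Truth genotypes as individuals x SNP-id matrix of two-letter strings."""
        if self.genotypes.empty:
            return pd.DataFrame(index=self.individuals)
        df = self.genotypes.assign(
            snp_id=lambda d: d.locus_id + ":" + d.pos.astype(str)
        )
        mat = df.pivot(index="individual", columns="snp_id", values="genotype")
        return mat.reindex(index=self.individuals, columns=self.snp_ids())


def _folded_sfs_counts(rng: np.random.Generator, n_copies: int, size: int) -> np.ndarray:
    """Derived-allele counts i in 1..n_copies-1 with probability proportional to 1/i."""
    i = np.arange(1, n_copies)
    p = (1.0 / i) / np.sum(1.0 / i)
    return rng.choice(i, size=size, p=p)


def simulate_dataset(config: SimConfig) -> tuple[PileSet, SimTruth]:
    """Generate piles plus ground truth; bit-identical for identical config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, L, c = config.n_individuals, config.locus_length, config.copy_number
    individuals = [f"ind{i + 1}" for i in range(n)]
    piles = PileSet(individuals=individuals)

    geno_rows: list[tuple] = []
    para_rows: list[tuple] = []
    width = len(str(config.n_loci))

    for li in range(config.n_loci):
        locus_id = f"locus{li + 1:0{width}d}"
        ref = rng.integers(0, 4, size=L)
        is_para = bool(rng.random() < config.paralog_fraction)

        # individual gene copies on the reference locus: (L, n, 2) base indices
        copies = np.broadcast_to(ref[:, None, None], (L, n, 2)).copy()
        seg_sites = np.flatnonzero(rng.random(L) < config.theta_sim)
        for pos in seg_sites:
            derived = (ref[pos] + rng.integers(1, 4)) % 4
            count = _folded_sfs_counts(rng, 2 * n, 1)[0]
            p = count / (2 * n)
            has_derived = rng.random((n, 2)) < p  # Hardy-Weinberg: copies independent
            copies[pos][has_derived] = derived
            for ind in range(n):
                pair = sorted(copies[pos, ind])
                geno_rows.append(
                    (locus_id, int(pos), individuals[ind],
                     BASES[pair[0]] + BASES[pair[1]], float(p))
                )

        # duplicate copies: fixed in all individuals, diverged at some sites
        dup = ref.copy()
        if is_para:
            div_sites = np.flatnonzero(rng.random(L) < config.paralog_divergence)
            dup[div_sites] = (ref[div_sites] + rng.integers(1, 4, size=len(div_sites))) % 4
        else:
            div_sites = np.array([], dtype=int)

        copies_total = 2 * c if is_para else 2
        comp = np.zeros((L, n, 4))
        for k in range(2):
            np.add.at(comp, (np.arange(L)[:, None], np.arange(n)[None, :], copies[:, :, k]), 1.0)
        if is_para:
            comp[np.arange(L), :, dup] += 2.0 * (c - 1)
        comp /= copies_total

        eps = config.error_rate
        read_p = comp * (1.0 - eps) + (1.0 - comp) * (eps / 3.0)
        lam = config.coverage_mean * (c if is_para else 1)
        depth = rng.poisson(lam, size=(L, n))
        counts = rng.multinomial(depth, read_p)

        piles.add_locus(Locus(locus_id, "".join(BASES[b] for b in ref), counts))
        para_rows.append(
            (locus_id, is_para, c if is_para else 1,
             ",".join(str(s) for s in div_sites), int(len(div_sites)))
        )

    genotypes = pd.DataFrame(
        geno_rows, columns=["locus_id", "pos", "individual", "genotype", "derived_freq"]
    )
    paralogs = pd.DataFrame(
        para_rows,
        columns=["locus_id", "is_paralog", "copy_number", "fixed_diff_sites", "n_fixed_diffs"],
    )
    truth = SimTruth(genotypes, paralogs, config, individuals)
    return piles, truth


def emulate_assay(
    truth: SimTruth, assay_fail_rate: float | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Assay-style genotype table: truth at SNP sites with random "FAIL" entries.

    Stands in for an independent single-SNP genotyping assay of the simulated
    SNPs; each (individual, SNP) entry fails independently with probability
    ``assay_fail_rate``.
    """
    rate = truth.config.assay_fail_rate if assay_fail_rate is None else float(assay_fail_rate)
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("assay_fail_rate must lie in [0, 1]")
    rng = np.random.default_rng(truth.config.seed + 1 if seed is None else seed)
    mat = truth.genotype_matrix().copy()
    if mat.empty:
        return mat
    fail = rng.random(mat.shape) < rate
    out = mat.where(~fail, "FAIL")
    return out


def simulate_individual_pileup(
    n_sites: int,
    depth_mean: float,
    het_rate: float,
    error_rate: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Piles for a single individual drawn exactly from the calling model.

    Each site is heterozygous (two distinct uniformly chosen bases) with
    probability ``het_rate``, else homozygous; depth is Poisson.  Returns the
    ``(n_sites, 4)`` count matrix and the true genotype index per site.
    Useful for parameter-recovery and calibration studies.
    """
    from .likelihood import HET_IDX, HOM_IDX, emission_matrix

    rng = np.random.default_rng(seed)
    is_het = rng.random(n_sites) < het_rate
    gidx = np.where(
        is_het,
        np.asarray(HET_IDX)[rng.integers(0, len(HET_IDX), n_sites)],
        np.asarray(HOM_IDX)[rng.integers(0, len(HOM_IDX), n_sites)],
    )
    em = emission_matrix(error_rate)
    depth = rng.poisson(depth_mean, size=n_sites)
    counts = rng.multinomial(depth, em[gidx])
    return counts, gidx


def simulate_hwe_snp_sites(
    n_sites: int,
    n_individuals: int,
    depth_mean: float,
    error_rate: float,
    seed: int = 0,
    freq_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Biallelic A/C SNP sites under Hardy-Weinberg at uniform allele frequencies.

    Single-locus truth (no paralogy): per site, each individual's genotype is
    binomial in the C allele at that site's frequency; reads follow the
    caller's emission model at Poisson depth.  Returns the
    ``(n_sites, n_individuals, 4)`` counts and the per-site C frequency.
    Intended for false-positive calibration of the paralogy LRT.
    """
    from .likelihood import emission_matrix

    rng = np.random.default_rng(seed)
    p = rng.uniform(freq_range[0], freq_range[1], size=n_sites)
    n_c = (rng.random((n_sites, n_individuals, 2)) < p[:, None, None]).sum(axis=2)
    geno_idx = np.select([n_c == 0, n_c == 1, n_c == 2], [0, 1, 4])  # AA, AC, CC
    em = emission_matrix(error_rate)
    depth = rng.poisson(depth_mean, size=(n_sites, n_individuals))
    counts = rng.multinomial(depth, em[geno_idx])
    return counts, p


def config_dict(config: SimConfig) -> dict:
    """Plain-dict view of a configuration (for manifests and truth tables)."""
    return asdict(config)
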