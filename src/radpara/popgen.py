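"""Diversity statistics: MAF, observed/expected heterozygosity (Nei unbiased), FIS.

Per-site statistics are computed from called genotypes only, so the sample
size ``n`` varies site by site.  With ``p_k`` the sample allele frequencies
over the ``2n`` called gene copies,

    Ho  = fraction of called individuals that are heterozygous
    Hs  = (2n / (2n - 1)) * (1 - sum_k p_k^2)        (Nei's unbiased gene diversity)
    Fis = 1 - Ho / Hs                                 (undefined when Hs = 0)

Sequence-level nucleotide diversity is the mean of the per-site Hs over every
site of the locus set, monomorphic sites included (length weighting), and is
reported as theta.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .likelihood import ALLELE_COUNTS, GENOTYPE_INDEX, IS_HET

# lookup tables with a trailing "missing" slot (index 10)
_ALLELE_LUT = np.vstack([ALLELE_COUNTS, np.zeros((1, 4), dtype=np.int64)])
_HET_LUT = np.concatenate([IS_HET.astype(np.int64), [0]])


def _canon(genotypes) -> np.ndarray:
    """Genotype strings -> indices 0..9, missing (None / './.' / NaN) -> 10."""
    out = np.empty(len(genotypes), dtype=np.int64)
    for i, g in enumerate(genotypes):
        if g is None or (isinstance(g, float) and np.isnan(g)) or g in ("./.", "", "NA"):
            out[i] = 10
            continue
        key = "".join(sorted(str(g).upper()))
        if key not in GENOTYPE_INDEX:
            raise ValueError(f"unrecognised genotype {g!r}")
        out[i] = GENOTYPE_INDEX[key]
    return out


def site_allele_counts(genotypes) -> tuple[np.ndarray, int]:
    """Gene-copy counts per base (4-vector) and the number of called individuals."""
    idx = _canon(genotypes)
    counts = _ALLELE_LUT[idx].sum(axis=0)
    return counts, int(np.sum(idx < 10))


def maf(genotypes) -> float:
    """Minor allele frequency among called gene copies (two per called individual).

    The frequency of the second-most-frequent allele; 0 at monomorphic sites,
    NaN when no genotype is called.  Rank ties break lexicographically by base.
    """
    counts, n = site_allele_counts(genotypes)
    if n == 0:
        return float("nan")
    order = np.lexsort((np.arange(4), -counts))
    return float(counts[order[1]] / (2 * n))


def nei_stats(genotypes) -> tuple[float, float, float]:
    """(Ho, Hs, Fis) at one site from called genotypes; needs >= 2 called."""
    idx = _canon(genotypes)
    called = idx[idx < 10]
    n = len(called)
    if n < 2:
        return (float("nan"), float("nan"), float("nan"))
    ho = float(_HET_LUT[called].sum() / n)
    counts = _ALLELE_LUT[called].sum(axis=0)
    tot = 2 * n
    hs = float(tot / (tot - 1) * (1.0 - np.sum((counts / tot) ** 2)))
    fis = float("nan") if hs == 0.0 else float(1.0 - ho / hs)
    return ho, hs, fis


def nucleotide_diversity(calls_by_site, total_sites: int) -> float:
    """Mean per-site unbiased gene diversity over a locus set (theta).

    ``calls_by_site`` yields the called-genotype list of each variable or
    covered site; ``total_sites`` is the summed length of the loci, so
    monomorphic and uncovered sites enter the average as zeros.
    """
    if total_sites <= 0:
        return float("nan")
    acc = 0.0
    for genotypes in calls_by_site:
        _, hs, _ = nei_stats(genotypes)
        if np.isfinite(hs):
            acc += hs
    return acc / total_sites


# ---------------------------------------------------------------------------
# vectorised per-site statistics used by the depth sweep
# ---------------------------------------------------------------------------

def stats_from_call_indices(geno_idx: np.ndarray) -> pd.DataFrame:
    """Per-site MAF/Ho/Hs/Fis from a (n_sites, n_individuals) call-index matrix.

    Missing calls are encoded as -1 (or 10).  Returns one row per site with
    the number of called individuals, number of distinct alleles, the major
    and minor allele indices and the four statistics; sites with < 2 called
    individuals get NaN statistics.
    """
    idx = np.where(geno_idx < 0, 10, geno_idx)
    ac = _ALLELE_LUT[idx].sum(axis=1)  # (S, 4)
    n_called = (idx < 10).sum(axis=1)
    tot = 2 * n_called
    n_alleles = (ac > 0).sum(axis=1)

    # descending count order with lexicographic tie-break by base index
    composite = ac * 4 + (3 - np.arange(4))[None, :]
    order = np.argsort(-composite, axis=1, kind="stable")  # (S, 4)
    major = order[:, 0]
    minor = order[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        maf_v = ac[np.arange(len(ac)), minor] / tot
        ho = _HET_LUT[idx].sum(axis=1) / n_called
        hs = np.where(
            tot > 2,
            tot / np.maximum(tot - 1, 1) * (1.0 - ((ac / np.maximum(tot, 1)[:, None]) ** 2).sum(axis=1)),
            np.nan,
        )
        fis = np.where(hs > 0, 1.0 - ho / hs, np.nan)
    bad = n_called < 2
    for arr in (maf_v, ho, hs, fis):
        arr[bad] = np.nan
    return pd.DataFrame(
        {
            "n_called": n_called,
            "n_alleles": n_alleles,
            "major": major,
            "minor": minor,
            "maf": maf_v,
            "ho": ho,
            "hs": hs,
            "fis": fis,
        }
    )


def hs_vector(geno_idx: np.ndarray) -> np.ndarray:
    """Per-site unbiased Hs (0 where fewer than 2 genotypes are called)."""
    idx = np.where(geno_idx < 0, 10, geno_idx)
    ac = _ALLELE_LUT[idx].sum(axis=1)
    n_called = (idx < 10).sum(axis=1)
    tot = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        hs = tot / np.maximum(tot - 1, 1) * (1.0 - ((ac / np.maximum(tot, 1)[:, None]) ** 2).sum(axis=1))
    hs[n_called < 2] = 0.0
    return hs


def summary_table(
    snp_table: pd.DataFrame,
    locus_status: pd.DataFrame,
    depth_label=None,
    mean_over_polymorphic: bool = True,
) -> pd.DataFrame:
    """Locus/SNP summary computed separately for paralogous and other loci.

    ``snp_table`` needs columns ``locus_id``, ``n_alleles`` and ``flag`` (one
    row per SNP); ``locus_status`` needs ``locus_id`` and ``is_paralog`` and
    defines the locus universe (loci absent from ``snp_table`` count as
    monomorphic).  ``mean_over_polymorphic`` selects the denominator of the
    mean-SNPs-per-locus row (polymorphic loci by default).
    """
    need = {"locus_id", "is_paralog"}
    if not need <= set(locus_status.columns):
        raise ValueError(f"locus_status must have columns {sorted(need)}")
    rows = {}
    for name, para in (("paralogous", True), ("nonparalogous", False)):
        loci = locus_status.loc[locus_status.is_paralog == para, "locus_id"]
        snps = snp_table[snp_table.locus_id.isin(set(loci))]
        n_loci = len(loci)
        per_locus = snps.groupby("locus_id").size().reindex(loci, fill_value=0)
        n_poly = int((per_locus > 0).sum())
        n_snps = len(snps)

        def pct(x, denom):
            return 100.0 * x / denom if denom else float("nan")

        mean_denom = n_poly if mean_over_polymorphic else n_loci
        n_pass = int((snps.flag == "PASS").sum()) if "flag" in snps else 0
        para_loci_with_pass = (
            int(snps.loc[snps.flag == "PASS", "locus_id"].nunique())
            if ("flag" in snps and para)
            else 0
        )
        rows[name] = {
            "n_loci": n_loci,
            "pct_monomorphic": pct(n_loci - n_poly, n_loci),
            "pct_1or2_snps": pct(int(per_locus.isin([1, 2]).sum()), n_loci),
            "pct_gt2_snps": pct(int((per_locus > 2).sum()), n_loci),
            "n_snps": n_snps,
            "mean_snps_per_locus": (n_snps / mean_denom) if mean_denom else float("nan"),
            "pct_biallelic": pct(int((snps.n_alleles == 2).sum()), n_snps),
            "pct_multiallelic": pct(int((snps.n_alleles > 2).sum()), n_snps),
            "n_para_loci_with_pass": para_loci_with_pass if para else float("nan"),
            "pct_pass_of_total": pct(n_pass, n_snps) if para else float("nan"),
        }
    out = pd.DataFrame(rows)
    if depth_label is not None:
        out.columns = pd.MultiIndex.from_product([[depth_label], out.columns])
    return out
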