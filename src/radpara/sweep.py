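"""Minimum-depth sweep with and without paralog filtering.

This is the pipeline's core experiment: over a range of calling depth
thresholds (2x-20x by default, focal depths 4x and 18x) genotypes are called,
SNPs detected (a site is a SNP when at least two distinct alleles occur among
the called genotypes), every SNP site is run through the paralogy LRT, loci
are classified, and diversity statistics (theta, MAF, Ho/Hs/Fis) are computed
both on all loci and after removing paralogous loci.  The plug-in error rate
is estimated once from all piles and reused across depths so that depths stay
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import PileSet
from .genotyper import GenotypeCaller, estimate_global_error
from .likelihood import BASES
from .parafilter import classify_loci, test_site
from .popgen import hs_vector, stats_from_call_indices


@dataclass
class SweepConfig:
    depths: tuple[int, ...] = tuple(range(2, 21, 2))
    focal_depths: tuple[int, int] = (4, 18)
    th1: float = 0.95
    th2: float = 0.01
    error_rate: float | str = "auto"  # "auto": pooled ML estimate from the piles


@dataclass
class SweepResult:
    """Per-depth summaries plus the SNP tables behind the distributions."""

    table: pd.DataFrame                       # one row per depth
    snp_tables: dict[int, pd.DataFrame]       # per-depth SNP-level statistics
    locus_status: dict[int, pd.DataFrame]     # per-depth locus classification
    error_rate_hat: float
    config: SweepConfig = field(default_factory=SweepConfig)


def _locus_sizes(piles: PileSet) -> tuple[list[str], np.ndarray]:
    ids = piles.locus_ids
    sizes = np.array([piles.loci[lid].length for lid in ids])
    return ids, sizes


def snp_table_at_depth(
    piles: PileSet,
    min_depth: int,
    error_rate: float,
    th1: float = 0.95,
    th2: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Call genotypes at one depth and test every SNP site for paralogy.

    Returns the SNP table (one row per SNP with statistics, LRT numbers,
    flags and per-individual calls), the locus-status table and the full
    per-site genotype-index matrix (for diversity computations).
    """
    caller = GenotypeCaller(error_rate=error_rate, min_depth=min_depth, th1=th1).fit(
        np.zeros((1, 4))
    )
    stacked = piles.stacked_counts()            # (S, n_ind, 4)
    S, n_ind, _ = stacked.shape
    idx, _, _ = caller.predict_indices(stacked.reshape(-1, 4))
    geno_idx = idx.reshape(S, n_ind)

    site_stats = stats_from_call_indices(geno_idx)
    site_keys = piles.site_index()
    is_snp = (site_stats.n_alleles >= 2).to_numpy()

    rows = []
    results = []
    for s in np.flatnonzero(is_snp):
        lid, pos = site_keys[s]
        row = site_stats.iloc[s]
        counts = stacked[s]
        ac_order = _present_alleles(geno_idx[s])
        try:
            res = test_site(
                counts, ac_order, error_rate, th2=th2, min_depth=min_depth,
                locus_id=lid, pos=pos,
            )
        except ValueError:  # < 2 individuals at depth: tested nowhere, no flag
            res = None
        if res is not None:
            results.append(res)
        rows.append(
            {
                "locus_id": lid,
                "pos": pos,
                "alleles": "/".join(BASES[a] for a in ac_order),
                "n_called": int(row.n_called),
                "n_alleles": int(row.n_alleles),
                "maf": row.maf,
                "ho": row.ho,
                "hs": row.hs,
                "fis": row.fis,
                "lnL1": res.lnl1 if res else np.nan,
                "lnL2": res.lnl2 if res else np.nan,
                "lrt_stat": res.lrt_stat if res else np.nan,
                "p_value": res.p_value if res else np.nan,
                "flag": res.flag if res else "NA",
            }
        )
    snp_df = pd.DataFrame(
        rows,
        columns=[
            "locus_id", "pos", "alleles", "n_called", "n_alleles", "maf", "ho",
            "hs", "fis", "lnL1", "lnL2", "lrt_stat", "p_value", "flag",
        ],
    )
    status = classify_loci(results, loci=piles.locus_ids)
    status_df = pd.DataFrame(
        [
            {
                "locus_id": st.locus_id,
                "is_paralog": st.is_paralog,
                "n_para_sites": st.n_para_sites,
                "n_pass_sites": st.n_pass_sites,
            }
            for st in status
        ]
    )
    return snp_df, status_df, geno_idx


def _present_alleles(site_geno_idx: np.ndarray) -> list[int]:
    """Alleles among called genotypes, most frequent first (lexicographic ties)."""
    from .popgen import _ALLELE_LUT

    idx = np.where(site_geno_idx < 0, 10, site_geno_idx)
    ac = _ALLELE_LUT[idx].sum(axis=0)
    composite = ac * 4 + (3 - np.arange(4))
    order = np.argsort(-composite, kind="stable")
    return [int(a) for a in order if ac[a] > 0]


def theta_for_loci(
    geno_idx: np.ndarray, piles: PileSet, keep: set[str] | None = None
) -> float:
    """Length-weighted mean per-site Hs over the given loci (all when ``keep=None``)."""
    ids, sizes = _locus_sizes(piles)
    hs = hs_vector(geno_idx)
    mask = np.ones(len(hs), dtype=bool)
    if keep is not None:
        locus_of_site = np.repeat(np.arange(len(ids)), sizes)
        keep_idx = {i for i, lid in enumerate(ids) if lid in keep}
        mask = np.isin(locus_of_site, list(keep_idx))
    total = int(mask.sum())
    return float(hs[mask].sum() / total) if total else float("nan")


def coverage_by_class(
    piles: PileSet, locus_status
) -> tuple[float, float, float]:
    """Mean per-site depth of paralogous vs non-paralogous loci and their ratio.

    Depth is averaged over sites and individuals within each class; the ratio
    is NaN when either class is empty.  Elevated paralog coverage (about
    copy-number-fold) is the expected diagnostic signature of collapse.
    """
    if isinstance(locus_status, pd.DataFrame):
        para_ids = set(locus_status.loc[locus_status.is_paralog, "locus_id"])
        known = set(locus_status.locus_id)
    else:
        para_ids = {st.locus_id for st in locus_status if st.is_paralog}
        known = {st.locus_id for st in locus_status}
    mean_para: list[float] = []
    mean_non: list[float] = []
    for lid, locus in piles.loci.items():
        if lid not in known:
            continue
        m = float(locus.counts.sum(axis=2).mean())
        (mean_para if lid in para_ids else mean_non).append(m)
    cov_para = float(np.mean(mean_para)) if mean_para else float("nan")
    cov_non = float(np.mean(mean_non)) if mean_non else float("nan")
    ratio = cov_para / cov_non if (mean_para and mean_non and cov_non > 0) else float("nan")
    return cov_para, cov_non, float(ratio)


def compare_distributions(x, y, paired: bool = False) -> tuple[float, float]:
    """Two-sided Wilcoxon comparison of two samples.

    Unpaired: rank-sum (Mann-Whitney normal approximation with tie and
    continuity corrections).  Paired: signed-rank.  All-tied inputs return a
    p-value of 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired comparison needs equal-length samples")
        d = x - y
        if np.all(d == 0):
            return 0.0, 1.0
        res = sps.wilcoxon(x, y, zero_method="wilcox", correction=True,
                           alternative="two-sided", method="approx")
        return float(res.statistic), float(res.pvalue)
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided", use_continuity=True,
                           method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def run_depth_sweep(piles: PileSet, config: SweepConfig | None = None) -> SweepResult:
    """Run the full depth sweep; deterministic given the piles."""
    config = config or SweepConfig()
    stacked = piles.stacked_counts().reshape(-1, 4)
    if config.error_rate == "auto":
        eps = estimate_global_error(stacked)
    else:
        eps = float(config.error_rate)

    rows = []
    snp_tables: dict[int, pd.DataFrame] = {}
    locus_status: dict[int, pd.DataFrame] = {}
    for depth in config.depths:
        snp_df, status_df, geno_idx = snp_table_at_depth(
            piles, depth, eps, th1=config.th1, th2=config.th2
        )
        snp_tables[depth] = snp_df
        locus_status[depth] = status_df

        # loci analysable at this depth: >= 1 site with >= 2 called genotypes
        ids, sizes = _locus_sizes(piles)
        locus_of_site = np.repeat(np.arange(len(ids)), sizes)
        called2 = (geno_idx >= 0).sum(axis=1) >= 2
        analysable = {ids[i] for i in np.unique(locus_of_site[called2])}

        para_ids = set(status_df.loc[status_df.is_paralog, "locus_id"])
        n_para = len(para_ids & analysable)
        nonpara = analysable - para_ids

        theta_all = theta_for_loci(geno_idx, piles, analysable if analysable else None)
        theta_np = theta_for_loci(geno_idx, piles, nonpara) if nonpara else float("nan")
        restricted = status_df[status_df.locus_id.isin(analysable)]
        cov_p, cov_n, ratio = coverage_by_class(piles, restricted)

        snp_np = snp_df[~snp_df.locus_id.isin(para_ids)]
        rows.append(
            {
                "min_depth": depth,
                "n_loci": len(analysable),
                "n_para_loci": n_para,
                "pct_para": 100.0 * n_para / len(analysable) if analysable else float("nan"),
                "n_snps": len(snp_df),
                "n_snps_nonpara": len(snp_np),
                "n_called_genotypes": int((geno_idx >= 0).sum()),
                "theta_all": theta_all,
                "theta_nonpara": theta_np,
                "error_rate_hat": eps,
                "mean_cov_para": cov_p,
                "mean_cov_nonpara": cov_n,
                "cov_ratio": ratio,
                "maf_median_all": float(snp_df.maf.median()) if len(snp_df) else float("nan"),
                "maf_median_nonpara": float(snp_np.maf.median()) if len(snp_np) else float("nan"),
                "fis_median_all": float(snp_df.fis.median()) if len(snp_df) else float("nan"),
                "fis_median_nonpara": float(snp_np.fis.median()) if len(snp_np) else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    return SweepResult(table, snp_tables, locus_status, eps, config)
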