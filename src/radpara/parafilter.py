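"""Likelihood-ratio paralogy filter: one-locus Hardy-Weinberg vs collapsed duplicate.

For each candidate SNP (major/minor allele pair ``a``/``b``) two models of the
per-individual piles are maximised over one free parameter each:

* one-locus: each individual carries an unobserved genotype in {aa, ab, bb}
  drawn with Hardy-Weinberg weights at allele frequency ``p``; the likelihood
  marginalises the genotype and maximises over ``p``.
* two-locus: two collapsed diverged copies feed every individual's reads, so
  each read comes from the ``a``-carrying copy with the same shared
  contribution ratio ``r`` in every individual (the duplication is fixed);
  the likelihood maximises over ``r``.  This model predicts an excess of
  heterozygote-looking piles.

The statistic is ``max(0, 2 (lnL2 - lnL1))``.  The two models are not nested,
so a chi-square(1) upper tail is used as a pragmatic calibration of the
p-value (verified by simulation to keep the false-positive rate at or below
the nominal threshold); a site is flagged ``PARA`` when ``p < th2`` and the
two-locus model actually fits better.  A locus is paralogous as soon as one of
its sites is flagged.

Both likelihoods use the same per-read emission model as the genotype caller
(plug-in error rate) and exclude individuals below the depth threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .likelihood import BASES, BASE_INDEX, emission_matrix
from .genotyper import golden_section_max

PASS = "PASS"
PARA = "PARA"

_GRID = np.linspace(0.0, 1.0, 1001)


@dataclass
class ParaTestResult:
    """Per-site paralogy test outcome."""

    locus_id: str
    pos: int
    alleles: tuple[str, str]  # (major, minor)
    lnl1: float
    lnl2: float
    lrt_stat: float
    p_value: float
    flag: str  # PASS or PARA
    p_hat: float
    r_hat: float
    n_individuals_used: int


@dataclass
class LocusParaStatus:
    """Per-locus paralogy bookkeeping (paralogous iff >= 1 PARA site)."""

    locus_id: str
    is_paralog: bool
    n_para_sites: int
    n_pass_sites: int


def _allele_indices(alleles) -> tuple[int, int]:
    a, b = alleles
    ia = BASE_INDEX[a.upper()] if isinstance(a, str) else int(a)
    ib = BASE_INDEX[b.upper()] if isinstance(b, str) else int(b)
    if ia == ib:
        raise ValueError("the two alleles must differ")
    return ia, ib


def _filter_depth(counts: np.ndarray, min_depth: int) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("site piles must have shape (n_individuals, 4)")
    return counts[counts.sum(axis=1) >= min_depth]


def one_locus_loglik(
    counts, alleles, error_rate: float, min_depth: int = 1
) -> tuple[float, float]:
    """Maximised one-locus (Hardy-Weinberg) log-likelihood and allele frequency.

    ``counts`` holds one pile per individual, shape (n_individuals, 4);
    individuals below ``min_depth`` are excluded, and ``p_hat`` is the
    frequency of the first allele.  Optimised on a 1001-point grid followed by
    golden-section refinement.
    """
    ia, ib = _allele_indices(alleles)
    kept = _filter_depth(counts, min_depth)
    if len(kept) < 2:
        raise ValueError("need >= 2 individuals passing the depth threshold")

    em = emission_matrix(error_rate)
    geno_em = np.stack([em[_pair_index(ia, ia)], em[_pair_index(ia, ib)], em[_pair_index(ib, ib)]])
    with np.errstate(divide="ignore"):
        log_em = np.log(geno_em)
    log_em[~np.isfinite(log_em)] = -1e30
    ll_geno = kept @ log_em.T  # (m, 3): loglik under aa, ab, bb
    m_i = ll_geno.max(axis=1, keepdims=True)
    comp = np.exp(ll_geno - m_i)  # safe: rows scaled to max 1

    def objective(p: float) -> float:
        w = np.array([p * p, 2.0 * p * (1.0 - p), (1.0 - p) * (1.0 - p)])
        mix = comp @ w
        with np.errstate(divide="ignore"):
            return float(np.sum(np.log(mix) + m_i[:, 0]))

    # vectorised grid pass: HWE weights for every grid frequency at once
    W = np.stack([_GRID**2, 2.0 * _GRID * (1.0 - _GRID), (1.0 - _GRID) ** 2], axis=1)
    with np.errstate(divide="ignore"):
        vals = np.log(comp @ W.T).sum(axis=0) + m_i.sum()
    k = int(np.argmax(vals))
    lo = _GRID[max(k - 1, 0)]
    hi = _GRID[min(k + 1, len(_GRID) - 1)]
    p_hat, lnl1 = golden_section_max(objective, lo, hi, tol=1e-10)
    if vals[k] > lnl1:  # golden window never loses to its own grid centre
        p_hat, lnl1 = _GRID[k], vals[k]
    return float(lnl1), float(p_hat)


def two_locus_loglik(
    counts, alleles, error_rate: float, min_depth: int = 1
) -> tuple[float, float]:
    """Maximised two-locus (collapsed duplicate) log-likelihood and copy ratio.

    Every read is emitted from the first-allele copy with shared probability
    ``r`` and from the second-allele copy otherwise, then mis-read with the
    symmetric error model; ``r`` is common to all individuals.
    """
    ia, ib = _allele_indices(alleles)
    kept = _filter_depth(counts, min_depth)
    if len(kept) < 2:
        raise ValueError("need >= 2 individuals passing the depth threshold")

    em = emission_matrix(error_rate)
    e_a = em[_pair_index(ia, ia)]  # emission of a read drawn from the a-copy
    e_b = em[_pair_index(ib, ib)]

    def objective(r: float) -> float:
        p_read = r * e_a + (1.0 - r) * e_b
        with np.errstate(divide="ignore"):
            logp = np.log(p_read)
        logp[~np.isfinite(logp)] = -1e30
        val = float((kept @ logp).sum())
        return val if val > -1e25 else -np.inf

    # vectorised grid pass over the copy-contribution ratio
    p_grid = np.outer(_GRID, e_a) + np.outer(1.0 - _GRID, e_b)  # (grid, 4)
    with np.errstate(divide="ignore"):
        logp_grid = np.log(p_grid)
    logp_grid[~np.isfinite(logp_grid)] = -1e30
    vals = (kept @ logp_grid.T).sum(axis=0)
    vals[vals < -1e25] = -np.inf
    k = int(np.argmax(vals))
    lo = _GRID[max(k - 1, 0)]
    hi = _GRID[min(k + 1, len(_GRID) - 1)]
    r_hat, lnl2 = golden_section_max(objective, lo, hi, tol=1e-10)
    if vals[k] > lnl2:
        r_hat, lnl2 = _GRID[k], vals[k]
    return float(lnl2), float(r_hat)


def _pair_index(i: int, j: int) -> int:
    i, j = min(i, j), max(i, j)
    # index of unordered pair (i, j) in the canonical genotype ordering
    return sum(4 - k for k in range(i)) + (j - i)


def para_lrt(
    counts,
    alleles,
    error_rate: float,
    th2: float = 0.01,
    min_depth: int = 1,
    locus_id: str = "",
    pos: int = 0,
) -> ParaTestResult:
    """Likelihood-ratio paralogy test of one biallelic site."""
    lnl1, p_hat = one_locus_loglik(counts, alleles, error_rate, min_depth)
    lnl2, r_hat = two_locus_loglik(counts, alleles, error_rate, min_depth)
    lrt = max(0.0, 2.0 * (lnl2 - lnl1))
    p_value = float(chi2.sf(lrt, df=1))
    flag = PARA if (p_value < th2 and lnl2 > lnl1) else PASS
    n_used = int((_filter_depth(counts, min_depth)).shape[0])
    a, b = alleles
    a = a if isinstance(a, str) else BASES[a]
    b = b if isinstance(b, str) else BASES[b]
    return ParaTestResult(
        locus_id, pos, (a.upper(), b.upper()), lnl1, lnl2, lrt, p_value, flag,
        p_hat, r_hat, n_used,
    )


def test_site(
    counts,
    alleles,
    error_rate: float,
    th2: float = 0.01,
    min_depth: int = 1,
    locus_id: str = "",
    pos: int = 0,
) -> ParaTestResult:
    """Test a site with two or more observed alleles.

    Biallelic sites run one LRT.  Tri/tetra-allelic sites test every allele
    sub-pair and are flagged PARA if any sub-pair is; the reported numbers are
    those of the sub-pair with the largest statistic.
    """
    alleles = [a if isinstance(a, str) else BASES[a] for a in alleles]
    if len(alleles) < 2:
        raise ValueError("need at least two alleles to test a site")
    best: ParaTestResult | None = None
    for i in range(len(alleles)):
        for j in range(i + 1, len(alleles)):
            res = para_lrt(
                counts, (alleles[i], alleles[j]), error_rate, th2, min_depth,
                locus_id, pos,
            )
            if best is None or res.lrt_stat > best.lrt_stat:
                best = res
    assert best is not None
    return best


def classify_loci(
    results, loci: list[str] | None = None
) -> list[LocusParaStatus]:
    """Per-locus paralogy status from site-level test results.

    ``loci`` optionally supplies the full locus universe so that loci with no
    tested site appear (as non-paralogous with zero counts).  Skipped /
    untested sites never mark a locus paralogous.
    """
    para: dict[str, int] = {}
    ok: dict[str, int] = {}
    order: list[str] = list(loci) if loci is not None else []
    seen = set(order)
    for res in results:
        if res.locus_id not in seen:
            seen.add(res.locus_id)
            order.append(res.locus_id)
        if res.flag == PARA:
            para[res.locus_id] = para.get(res.locus_id, 0) + 1
        else:
            ok[res.locus_id] = ok.get(res.locus_id, 0) + 1
    return [
        LocusParaStatus(
            locus_id=lid,
            is_paralog=para.get(lid, 0) >= 1,
            n_para_sites=para.get(lid, 0),
            n_pass_sites=ok.get(lid, 0),
        )
        for lid in order
    ]


def results_table(results) -> pd.DataFrame:
    """Site-level test results as a tidy table."""
    rows = [
        {
            "locus_id": r.locus_id,
            "pos": r.pos,
            "alleles": "/".join(r.alleles),
            "lnL1": r.lnl1,
            "lnL2": r.lnl2,
            "lrt_stat": r.lrt_stat,
            "p_value": r.p_value,
            "flag": r.flag,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["locus_id", "pos", "alleles", "lnL1", "lnL2", "lrt_stat", "p_value", "flag"],
    )


class ParalogLRTFilter(BaseEstimator):
    """Estimator wrapper around the per-site LRT.

    ``X`` rows are sites; each row is an ``(n_individuals * 4)`` flattened
    pile block (or a ``(n_sites, n_individuals, 4)`` stack).  ``fit`` resolves
    the plug-in error rate; ``predict`` returns ``"PASS"``/``"PARA"`` per site
    (``"NA"`` where fewer than two individuals pass the depth threshold), with
    the tested alleles inferred from the pooled reads when not supplied.
    """

    def __init__(self, error_rate="auto", min_depth: int = 4, th2: float = 0.01):
        self.error_rate = error_rate
        self.min_depth = min_depth
        self.th2 = th2

    @staticmethod
    def _as_sites(X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 2:
            if X.shape[1] % 4:
                raise ValueError("flattened rows must hold 4 counts per individual")
            X = X.reshape(X.shape[0], -1, 4)
        if X.ndim != 3 or X.shape[2] != 4:
            raise ValueError("expected sites of shape (n_sites, n_individuals, 4)")
        return X

    def fit(self, X, y=None):
        X = self._as_sites(X)
        if self.error_rate == "auto":
            from .genotyper import estimate_global_error

            self.error_rate_ = estimate_global_error(X.reshape(-1, 4))
        else:
            self.error_rate_ = float(self.error_rate)
        return self

    def predict(self, X, alleles=None) -> np.ndarray:
        if not hasattr(self, "error_rate_"):
            raise RuntimeError("ParalogLRTFilter must be fitted before predicting")
        X = self._as_sites(X)
        flags = []
        for s, site in enumerate(X):
            if alleles is not None:
                pair = alleles[s]
            else:
                pooled = site.sum(axis=0)
                order = np.lexsort((np.arange(4), -pooled))
                pair = (BASES[order[0]], BASES[order[1]])
                if pooled[order[1]] == 0:
                    flags.append("NA")
                    continue
            kept = site[site.sum(axis=1) >= self.min_depth]
            if len(kept) < 2:
                flags.append("NA")
                continue
            flags.append(
                test_site(site, pair, self.error_rate_, self.th2, self.min_depth).flag
            )
        return np.asarray(flags)
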