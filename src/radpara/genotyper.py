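"""Diploid genotype calling and joint ML estimation of error rate and heterozygosity.

Calling uses a flat prior over the 10 unordered genotypes: a genotype is
emitted only when the pile depth reaches ``min_depth`` and the posterior of the
best genotype reaches ``th1`` (0.95 by default, the threshold used throughout
the pipeline); otherwise the call is missing.

``ErrorDiversityEstimator`` fits, per individual, the two-parameter mixture

    sum_sites log[ (1-H) * P_hom(counts | eps) + H * P_het(counts | eps) ]

where ``P_hom`` averages the four homozygote likelihoods and ``P_het`` the six
heterozygote likelihoods.  ``H`` is the per-site probability that the
individual is heterozygous and is reported as the individual's diversity
(theta); ``eps`` is the per-base error rate.  Optimisation is by alternating
bounded golden-section sweeps, which is derivative-free and fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .likelihood import (
    GENOTYPE_STRINGS,
    HET_IDX,
    HOM_IDX,
    genotype_log_likelihoods,
    genotype_posteriors,
)

MISSING = "./."

_LOG4 = np.log(4.0)
_LOG6 = np.log(6.0)
_LOG10 = np.log(10.0)

PARAM_LO = 1e-8
PARAM_HI = 0.25


@dataclass
class GenotypeCall:
    """One individual's call at one site: unordered base pair or missing."""

    individual: str | None
    genotype: str | None  # two-letter string, or None when missing
    posterior: float
    depth: int

    @property
    def is_missing(self) -> bool:
        return self.genotype is None


@dataclass
class IndividualMLEstimate:
    """Joint ML estimate of heterozygosity (theta) and error rate for one individual."""

    heterozygosity_hat: float
    error_rate_hat: float
    n_sites_used: int
    log_likelihood: float


class EstimationError(RuntimeError):
    """Raised when too few usable sites exist to estimate parameters."""


def golden_section_max(f, lo: float, hi: float, tol: float = 1e-8):
    """Maximise a scalar function on [lo, hi] by golden-section search."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = float(lo), float(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = c if fc >= fd else d
    return x, max(fc, fd)


def _as_count_matrix(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim == 3 and X.shape[-1] == 4:  # (sites, individuals, 4) stacks flatten fine
        X = X.reshape(-1, 4)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError("expected a pile matrix of shape (n_sites, 4)")
    if np.any(X < 0):
        raise ValueError("read counts must be non-negative")
    return X.astype(np.int64, copy=False)


def _compress_rows(X: np.ndarray):
    """Unique count rows with multiplicities (piles repeat heavily at low depth)."""
    uniq, weight = np.unique(X, axis=0, return_counts=True)
    return uniq, weight.astype(np.float64)


def _hom_het_logliks(uniq: np.ndarray, eps: float):
    ll = genotype_log_likelihoods(uniq, eps)
    log_p_hom = logsumexp(ll[:, HOM_IDX], axis=1) - _LOG4
    log_p_het = logsumexp(ll[:, HET_IDX], axis=1) - _LOG6
    return log_p_hom, log_p_het


def _mixture_loglik(uniq, weight, het_rate: float, eps: float) -> float:
    log_p_hom, log_p_het = _hom_het_logliks(uniq, eps)
    site = np.logaddexp(np.log1p(-het_rate) + log_p_hom, np.log(het_rate) + log_p_het)
    return float(weight @ site)


def _flat_marginal_loglik(uniq, weight, eps: float) -> float:
    ll = genotype_log_likelihoods(uniq, eps)
    return float(weight @ (logsumexp(ll, axis=1) - _LOG10))


class GenotypeCaller(BaseEstimator):
    """Genotype caller over 4-base count piles.

    Parameters
    ----------
    error_rate
        Per-base error rate, or ``"auto"`` to estimate it from the piles given
        to :meth:`fit` by maximising the flat-prior genotype-marginal
        likelihood pooled over all rows.
    min_depth
        Minimum read depth for a pile to be callable.
    th1
        Posterior-probability threshold; must exceed 0.5 so the argmax
        genotype is unique whenever it is called.
    """

    def __init__(self, error_rate="auto", min_depth: int = 4, th1: float = 0.95):
        self.error_rate = error_rate
        self.min_depth = min_depth
        self.th1 = th1

    def _validate(self) -> None:
        if not 0.5 < self.th1 <= 1.0:
            raise ValueError(f"th1 must lie in (0.5, 1], got {self.th1}")
        if self.min_depth < 1:
            raise ValueError(f"min_depth must be >= 1, got {self.min_depth}")

    def fit(self, X, y=None):
        """Resolve the working error rate (estimating it when ``"auto"``)."""
        self._validate()
        X = _as_count_matrix(X)
        if self.error_rate == "auto":
            self.error_rate_ = estimate_global_error(X)
        else:
            eps = float(self.error_rate)
            if not 0.0 <= eps <= 0.25:
                raise ValueError(f"error_rate must lie in [0, 0.25], got {eps}")
            self.error_rate_ = eps
        return self

    def _check_fitted(self):
        if not hasattr(self, "error_rate_"):
            raise RuntimeError("GenotypeCaller must be fitted before predicting")

    def predict_posterior(self, X) -> np.ndarray:
        """Flat-prior posterior over the 10 genotypes, shape (n_sites, 10)."""
        self._check_fitted()
        return genotype_posteriors(_as_count_matrix(X), self.error_rate_)

    def predict_indices(self, X):
        """Called genotype index in 0..9 (-1 when missing) plus posteriors and depths."""
        self._check_fitted()
        X = _as_count_matrix(X)
        post = genotype_posteriors(X, self.error_rate_)
        best = np.argmax(post, axis=1)
        best_post = post[np.arange(len(post)), best]
        depth = X.sum(axis=1)
        called = (depth >= self.min_depth) & (best_post >= self.th1) & (best_post > 0)
        idx = np.where(called, best, -1)
        return idx, best_post, depth

    def predict(self, X) -> np.ndarray:
        """Genotype strings (``"AG"`` style), ``"./."`` for missing calls."""
        idx, _, _ = self.predict_indices(X)
        lut = np.array(list(GENOTYPE_STRINGS) + [MISSING])
        return lut[idx]


class ErrorDiversityEstimator(BaseEstimator):
    """Joint ML estimator of per-individual heterozygosity and error rate.

    Fitted attributes: ``heterozygosity_hat_`` (theta), ``error_rate_hat_``,
    ``n_sites_used_`` and ``log_likelihood_``.
    """

    def __init__(self, min_depth: int = 1, min_sites: int = 100, tol: float = 1e-6):
        self.min_depth = min_depth
        self.min_sites = min_sites
        self.tol = tol

    def fit(self, X, y=None):
        X = _as_count_matrix(X)
        X = X[X.sum(axis=1) >= self.min_depth]
        if len(X) < self.min_sites:
            raise EstimationError(
                f"need >= {self.min_sites} sites with depth >= {self.min_depth}, "
                f"got {len(X)}"
            )
        uniq, weight = _compress_rows(X)

        het, eps = 0.01, 0.01
        ll = _mixture_loglik(uniq, weight, het, eps)
        for _ in range(100):
            eps, _ = golden_section_max(
                lambda e: _mixture_loglik(uniq, weight, het, e), PARAM_LO, PARAM_HI
            )
            het, new_ll = golden_section_max(
                lambda h: _mixture_loglik(uniq, weight, h, eps), PARAM_LO, PARAM_HI
            )
            if abs(new_ll - ll) < self.tol:
                ll = new_ll
                break
            ll = new_ll

        self.heterozygosity_hat_ = float(het)
        self.error_rate_hat_ = float(eps)
        self.n_sites_used_ = int(len(X))
        self.log_likelihood_ = float(ll)
        return self

    def estimate_(self) -> IndividualMLEstimate:
        return IndividualMLEstimate(
            heterozygosity_hat=self.heterozygosity_hat_,
            error_rate_hat=self.error_rate_hat_,
            n_sites_used=self.n_sites_used_,
            log_likelihood=self.log_likelihood_,
        )


def call_genotype(
    counts,
    error_rate: float,
    min_depth: int = 4,
    th1: float = 0.95,
    individual: str | None = None,
) -> GenotypeCall:
    """Call one individual's genotype from one pile (scalar convenience wrapper)."""
    caller = GenotypeCaller(error_rate=error_rate, min_depth=min_depth, th1=th1)
    caller.fit(np.zeros((1, 4)))
    idx, post, depth = caller.predict_indices(np.asarray(counts).reshape(1, 4))
    genotype = GENOTYPE_STRINGS[idx[0]] if idx[0] >= 0 else None
    return GenotypeCall(individual, genotype, float(post[0]), int(depth[0]))


def estimate_individual_ml(counts, min_depth: int = 1) -> IndividualMLEstimate:
    """Joint (theta, error-rate) ML fit for one individual's piles."""
    est = ErrorDiversityEstimator(min_depth=min_depth).fit(counts)
    return est.estimate_()


def estimate_global_error(counts, min_sites: int = 100) -> float:
    """Single pooled error rate maximising the flat-prior genotype marginal.

    Pools every pile (across individuals and sites) with depth >= 1; used as
    the plug-in error rate for genotype calling and the paralogy LRT.
    """
    X = _as_count_matrix(counts)
    X = X[X.sum(axis=1) >= 1]
    if len(X) < min_sites:
        raise EstimationError(f"need >= {min_sites} non-empty piles, got {len(X)}")
    uniq, weight = _compress_rows(X)
    eps, _ = golden_section_max(
        lambda e: _flat_marginal_loglik(uniq, weight, e), PARAM_LO, PARAM_HI
    )
    return float(eps)
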