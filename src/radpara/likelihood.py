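"""Multinomial read-emission model for diploid genotypes.

A site pile is a 4-vector of read counts over the bases A, C, G, T. Reads are
emitted independently from the individual's two gene copies with a symmetric
per-base error rate ``eps``: a read from a copy carrying base ``a`` shows ``a``
with probability ``1 - eps`` and each of the three other bases with probability
``eps / 3``.  For an unordered diploid genotype this gives the per-read emission
probabilities

* homozygote ``{a,a}``:   ``P(a) = 1 - eps``, ``P(other) = eps/3``
* heterozygote ``{a,b}``: ``P(a) = P(b) = (1-eps)/2 + eps/6``, ``P(other) = eps/3``

The multinomial coefficient is omitted consistently across genotypes: it
cancels in every posterior and likelihood ratio computed from these values.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: the 10 unordered diploid genotypes, ordered (AA, AC, AG, AT, CC, CG, CT, GG, GT, TT)
GENOTYPE_PAIRS = tuple((i, j) for i in range(4) for j in range(i, 4))
GENOTYPE_STRINGS = tuple(BASES[i] + BASES[j] for i, j in GENOTYPE_PAIRS)
GENOTYPE_INDEX = {s: k for k, s in enumerate(GENOTYPE_STRINGS)}
N_GENOTYPES = len(GENOTYPE_PAIRS)

HOM_IDX = np.array([k for k, (i, j) in enumerate(GENOTYPE_PAIRS) if i == j])
HET_IDX = np.array([k for k, (i, j) in enumerate(GENOTYPE_PAIRS) if i != j])
IS_HET = np.array([i != j for i, j in GENOTYPE_PAIRS])

#: number of copies of each base carried by each genotype (10 x 4)
ALLELE_COUNTS = np.zeros((N_GENOTYPES, 4), dtype=np.int64)
for _k, (_i, _j) in enumerate(GENOTYPE_PAIRS):
    ALLELE_COUNTS[_k, _i] += 1
    ALLELE_COUNTS[_k, _j] += 1

# log-probabilities below this are treated as "impossible" (true log 0)
_NEG_CAP = -1e25
_NEG_FILL = -1e30


def emission_matrix(error_rate: float) -> np.ndarray:
    """Per-read base emission probabilities, one row per genotype (10 x 4)."""
    eps = float(error_rate)
    if not 0.0 <= eps <= 0.25:
        raise ValueError(f"error_rate must lie in [0, 0.25], got {eps}")
    em = np.full((N_GENOTYPES, 4), eps / 3.0)
    for k, (i, j) in enumerate(GENOTYPE_PAIRS):
        if i == j:
            em[k, i] = 1.0 - eps
        else:
            em[k, i] = em[k, j] = 0.5 - eps / 3.0
    return em


def _log_emission(error_rate: float) -> np.ndarray:
    em = emission_matrix(error_rate)
    with np.errstate(divide="ignore"):
        le = np.log(em)
    # finite fill so that 0 * fill = 0 survives matrix products; capped back to -inf later
    le[~np.isfinite(le)] = _NEG_FILL
    return le


def genotype_log_likelihoods(counts: np.ndarray, error_rate: float) -> np.ndarray:
    """Log-likelihood of each of the 10 genotypes for each count row.

    Parameters
    ----------
    counts
        Integer array of shape ``(..., 4)`` of per-base read counts.
    error_rate
        Symmetric per-base error rate in ``[0, 0.25]``.

    Returns
    -------
    Array of shape ``(..., 10)``; impossible configurations are ``-inf``.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape[-1] != 4:
        raise ValueError("counts must have 4 trailing entries (A, C, G, T)")
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    ll = counts @ _log_emission(error_rate).T
    ll[ll < _NEG_CAP] = -np.inf
    return ll


def genotype_log_likelihood(counts, genotype: str, error_rate: float) -> float:
    """Log-likelihood of one unordered genotype (e.g. ``"AG"``) for one pile."""
    key = "".join(sorted(genotype.upper()))
    if key not in GENOTYPE_INDEX:
        raise ValueError(f"unknown genotype {genotype!r}")
    ll = genotype_log_likelihoods(np.asarray(counts, dtype=float), error_rate)
    return float(ll[..., GENOTYPE_INDEX[key]])


def genotype_posteriors(counts: np.ndarray, error_rate: float) -> np.ndarray:
    """Flat-prior posterior over the 10 genotypes for each count row.

    Rows whose every genotype has zero likelihood (including depth-0 rows)
    come back as all-zero rather than raising.
    """
    counts = np.asarray(counts, dtype=np.float64)
    ll = genotype_log_likelihoods(counts, error_rate)
    m = np.max(ll, axis=-1, keepdims=True)
    ok = np.isfinite(m)
    w = np.exp(np.where(ok, ll - np.where(ok, m, 0.0), -np.inf))
    tot = w.sum(axis=-1, keepdims=True)
    # depth-0 piles carry no information: posterior reported as all-zero, not uniform
    tot = np.where(counts.sum(axis=-1, keepdims=True) > 0, tot, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(tot > 0, w / tot, 0.0)
    return post
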