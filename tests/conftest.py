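"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import radpara as rp

BASES = "ACGT"
PAIRS = [(i, j) for i in range(4) for j in range(i, 4)]


def per_read_genotype_likelihood(counts, pair, eps) -> float:
    """Independent oracle: product of per-read emission probabilities.

    Written directly from the error model (a read from a copy with base x
    shows x w.p. 1-eps, each other base w.p. eps/3, the two copies equally
    likely), expanding the pile into individual reads.
    """
    i, j = pair
    lik = 1.0
    for base in range(4):
        for _ in range(int(counts[base])):
            p_from_i = (1.0 - eps) if base == i else eps / 3.0
            p_from_j = (1.0 - eps) if base == j else eps / 3.0
            lik *= 0.5 * p_from_i + 0.5 * p_from_j
    return lik


def oracle_posteriors(counts, eps) -> np.ndarray:
    """Flat-prior genotype posteriors by exhaustive per-read enumeration."""
    liks = np.array([per_read_genotype_likelihood(counts, pr, eps) for pr in PAIRS])
    if sum(counts) == 0:
        return np.zeros(10)
    tot = liks.sum()
    return liks / tot if tot > 0 else np.zeros(10)


def oracle_one_locus_loglik(counts, ia, ib, eps, grid_n=4001) -> float:
    """Grid-search oracle for the Hardy-Weinberg one-locus likelihood."""
    best = -np.inf
    for p in np.linspace(0, 1, grid_n):
        total = 0.0
        ok = True
        for row in counts:
            lik = 0.0
            for w, pair in (
                (p * p, (ia, ia)),
                (2 * p * (1 - p), (min(ia, ib), max(ia, ib))),
                ((1 - p) ** 2, (ib, ib)),
            ):
                lik += w * per_read_genotype_likelihood(row, pair, eps)
            if lik <= 0:
                ok = False
                break
            total += np.log(lik)
        if ok and total > best:
            best = total
    return best


def rank_sum_permutation_pvalue(x, y) -> tuple[float, float]:
    """Exhaustive-permutation oracle for the two-sided rank-sum test."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    ws = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    ws = np.array(ws)
    mean_w = ws.mean()
    p = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    u_obs = w_obs - n1 * (n1 + 1) / 2.0
    return float(u_obs), float(p)


@pytest.fixture(scope="session")
def paralog_sim():
    """Collapsed-paralog study-conditions simulation shared by the heavy tests."""
    config = rp.SimConfig(n_loci=1000, seed=20260)
    piles, truth = rp.simulate_dataset(config)
    return piles, truth


@pytest.fixture(scope="session")
def paralog_sweep(paralog_sim):
    """Full 2x-20x depth sweep over the shared paralog simulation."""
    piles, _ = paralog_sim
    return rp.run_depth_sweep(piles, rp.SweepConfig())


@pytest.fixture(scope="session")
def concordance_sim():
    """Paralog-free simulation at the assay-comparison conditions."""
    config = rp.SimConfig(
        n_loci=400, paralog_fraction=0.0, coverage_mean=12.0, error_rate=0.005,
        theta_sim=0.02, seed=907,
    )
    piles, truth = rp.simulate_dataset(config)
    return piles, truth


@pytest.fixture(scope="session")
def clean_sim():
    """Paralog-free simulation at deep coverage for accuracy/concordance checks."""
    config = rp.SimConfig(
        n_loci=400, paralog_fraction=0.0, coverage_mean=30.0, error_rate=0.01,
        theta_sim=0.03, seed=513,
    )
    piles, truth = rp.simulate_dataset(config)
    return piles, truth
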