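"""Shared fixtures and independent brute-force oracles.

The oracles recompute every quantity from scratch (direct summation,
full refits, exhaustive scans) and deliberately share no code with the
incremental implementation they check.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from dragonclust.mlcore import fit_gaussian


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # the eps_det / singularity warnings are expected in bulk runs
    logging.getLogger("dragonclust").setLevel(logging.ERROR)


@pytest.fixture
def square_points():
    """Four corners of a square: mean (1,1), ML covariance = identity."""
    return np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_mean_scatter(rows: np.ndarray):
    """Direct-summation mean and divisor-n scatter (loop, no matrix algebra)."""
    n, d = rows.shape
    mu = np.zeros(d)
    for r in rows:
        mu += r
    mu /= n
    sig = np.zeros((d, d))
    for r in rows:
        diff = r - mu
        sig += np.outer(diff, diff)
    return mu, sig / n


def brute_loglik(rows: np.ndarray) -> float:
    """Sum of Gaussian log-pdfs under the set's own ML fit (scipy oracle)."""
    from scipy.stats import multivariate_normal

    mu, sig = brute_mean_scatter(rows)
    return float(multivariate_normal(mu, sig, allow_singular=True).logpdf(rows).sum())


def refit_loglik(X: np.ndarray, members) -> float:
    """From-scratch fit of a member set; the reduced-set oracle for downdates."""
    return fit_gaussian(X, members).loglik


def brute_best_removal(X: np.ndarray, members) -> int:
    """Exhaustively refit every one-sample-removed subset; argmax likelihood."""
    members = sorted(int(m) for m in members)
    best_idx, best_l = None, -np.inf
    for i in members:
        reduced = [j for j in members if j != i]
        l = refit_loglik(X, reduced)
        if l > best_l + 1e-12:
            best_idx, best_l = i, l
    return best_idx


def random_instance(rng: np.random.Generator, n_max: int = 60, d_max: int = 8):
    """A random (n, d) Gaussian-ish sample matrix with d safely below n."""
    n = int(rng.integers(5, n_max + 1))
    d = int(rng.integers(1, min(d_max, n - 2) + 1))
    X = rng.standard_normal((n, d)) * rng.uniform(0.5, 2.0)
    X += rng.uniform(-3, 3, size=d)
    return X
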