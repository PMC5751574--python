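"""Gaussian maximum-likelihood machinery for one candidate cluster.

A candidate cluster is a subset of the rows of a sample matrix.  Its
log-likelihood under its own maximum-likelihood (ML) Gaussian fit has the
closed form

    L = -(1/2) n d - (n d / 2) log 2π - (n / 2) log|Σ|

where Σ is the ML scatter matrix (divisor ``n``, not ``n - 1``).  Removing a
single sample x̂ changes μ, Σ, |Σ| and L in closed form:

    μ* = μ - (x̂ - μ) / (n - 1)
    Σ* = n/(n-1) Σ - n/(n-1)² (x̂ - μ)(x̂ - μ)ᵀ
    |Σ*| = (n/(n-1))^d |Σ| (1 - P/(n-1)),   P = (x̂ - μ)ᵀ Σ⁻¹ (x̂ - μ)
    L* = L - ΔL

with ΔL a function of |Σ|, P, n and d only.  This module maintains those
sufficient statistics incrementally (O(d²) per removal, with periodic
refactorisation to bound floating-point drift) and exposes the selection rule
``argmax P``, which is equivalent to choosing the removal that maximally
increases L.

The divisor-n covariance is essential: both the determinant downdate and the
bound 0 ≤ P ≤ n - 1 for members rely on it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: floor applied to the determinant factor (1 - P/(n-1)) before taking its log
DEFAULT_EPS_DET = 1e-12

#: Σ is declared numerically singular when min eig < this ratio times max eig
_SINGULAR_EIG_RATIO = 1e-10

#: ridge is λ = _RIDGE_SCALE * trace(Σ)/d when Σ is singular
_RIDGE_SCALE = 1e-8

#: refactorise Σ⁻¹ and log|Σ| from scratch after this many rank-one downdates
DEFAULT_REFACTOR_EVERY = 50


class InvalidInputError(ValueError):
    """Raised on malformed inputs (bad shapes, non-member indices, too few samples)."""


class SingularCovarianceError(ValueError):
    """Raised when Σ is singular and the ridge fallback is disabled or useless."""


@dataclass
class ClusterState:
    """Sufficient statistics and cached likelihood of a candidate cluster.

    ``member_indices`` are row indices into the parent sample matrix, kept in
    ascending order so that argmax ties resolve to the smallest index.
    ``ridge`` records the regulariser actually added to Σ (0 when Σ was
    invertible as-is).
    """

    member_indices: np.ndarray
    n: int
    d: int
    mu: np.ndarray
    sigma: np.ndarray
    sigma_inv: np.ndarray
    log_det_sigma: float
    loglik: float
    ridge: float = 0.0
    updates_since_refactor: int = 0


@dataclass(frozen=True)
class RemovalStep:
    """One extraction step: which sample left and what it did to the likelihood."""

    removed_index: int
    mahal_sq: float        # P: squared Mahalanobis distance from μ under Σ
    delta_loglik: float    # ΔL, with L* = L - ΔL
    loglik_after: float    # L* of the cluster once the sample is gone


def gaussian_loglik(n: int, d: int, log_det_sigma: float) -> float:
    """Closed-form cluster log-likelihood from n, d and log|Σ| alone."""
    return -0.5 * n * d - 0.5 * n * d * math.log(2.0 * math.pi) - 0.5 * n * log_det_sigma


def _factorize(sigma: np.ndarray, *, allow_ridge: bool = True):
    """Return (sigma, sigma_inv, log_det, ridge), ridging Σ if near-singular."""
    d = sigma.shape[0]
    eigvals = np.linalg.eigvalsh(sigma)
    ridge = 0.0
    if eigvals[0] < _SINGULAR_EIG_RATIO * max(eigvals[-1], 0.0) or eigvals[0] <= 0.0:
        tr = float(np.trace(sigma))
        if not allow_ridge or tr <= 0.0:
            raise SingularCovarianceError(
                f"covariance is singular (min eig {eigvals[0]:.3e}); "
                "all samples may be identical"
            )
        ridge = _RIDGE_SCALE * tr / d
        sigma = sigma + ridge * np.eye(d)
        logger.warning("singular covariance; applied ridge %.3e", ridge)
    sign, log_det = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise SingularCovarianceError("covariance not positive definite after ridge")
    sigma_inv = np.linalg.inv(sigma)
    return sigma, sigma_inv, float(log_det), ridge


def fit_gaussian(
    X: np.ndarray,
    indices,
    *,
    allow_ridge: bool = True,
) -> ClusterState:
    """ML Gaussian fit of the indexed rows of ``X`` (mean and divisor-n scatter).

    Raises :class:`InvalidInputError` for fewer than two samples and
    :class:`SingularCovarianceError` when Σ cannot be made invertible.
    A warning is logged when d ≥ n (the scatter is then necessarily singular
    and only the ridge keeps the fit defined).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError("sample matrix must be 2-D (rows = samples)")
    indices = np.asarray(sorted(int(i) for i in np.asarray(indices).ravel()), dtype=np.intp)
    if indices.size < 2:
        raise InvalidInputError("a cluster needs at least 2 samples")
    if indices.size != np.unique(indices).size:
        raise InvalidInputError("duplicate member indices")
    n, d = indices.size, X.shape[1]
    if d >= n:
        logger.warning("d=%d >= n=%d: covariance is singular by construction", d, n)
    rows = X[indices]
    mu = rows.mean(axis=0)
    centred = rows - mu
    sigma = centred.T @ centred / n
    sigma = 0.5 * (sigma + sigma.T)
    sigma, sigma_inv, log_det, ridge = _factorize(sigma, allow_ridge=allow_ridge)
    return ClusterState(
        member_indices=indices,
        n=n,
        d=d,
        mu=mu,
        sigma=sigma,
        sigma_inv=sigma_inv,
        log_det_sigma=log_det,
        loglik=gaussian_loglik(n, d, log_det),
        ridge=ridge,
    )


def log_likelihood(state: ClusterState) -> float:
    """Cluster log-likelihood L of the state (closed form in n, d, log|Σ|)."""
    return gaussian_loglik(state.n, state.d, state.log_det_sigma)


def mahalanobis_p(state: ClusterState, x: np.ndarray) -> float:
    """Squared Mahalanobis distance P of ``x`` from the cluster centre.

    For a member of the cluster this satisfies 0 ≤ P ≤ n - 1 (a tight bound
    specific to the divisor-n covariance).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != state.d:
        raise InvalidInputError(f"x has length {x.size}, expected d={state.d}")
    diff = x - state.mu
    return float(diff @ state.sigma_inv @ diff)


def mahalanobis_members(state: ClusterState, X: np.ndarray) -> np.ndarray:
    """P for every current member, vectorised; one scan of the candidate set."""
    diffs = X[state.member_indices] - state.mu
    return np.einsum("ij,jk,ik->i", diffs, state.sigma_inv, diffs)


def delta_loglik_from_p(state: ClusterState, p: float, *, eps_det: float = DEFAULT_EPS_DET) -> float:
    """ΔL for removing a member at squared Mahalanobis distance ``p``.

    ΔL is strictly decreasing in P, so argmax P = argmin ΔL = argmax L*.
    When P approaches n - 1 the determinant factor 1 - P/(n-1) collapses; it
    is floored at ``eps_det`` and the candidate's ΔL is returned as -inf
    (removal maximally favoured) with a logged warning.
    """
    n, d = state.n, state.d
    factor = 1.0 - p / (n - 1)
    if factor < eps_det:
        logger.warning(
            "determinant factor %.3e below eps_det=%.1e (P=%.6g, n=%d); "
            "treating removal as infinitely favourable",
            factor, eps_det, p, n,
        )
        return -math.inf
    return (
        -0.5 * state.log_det_sigma
        + 0.5 * (n - 1) * math.log(factor)
        + 0.5 * (n - 1) * d * math.log(n / (n - 1))
        - 0.5 * d
        - 0.5 * d * math.log(2.0 * math.pi)
    )


def delta_l(state: ClusterState, x: np.ndarray, *, eps_det: float = DEFAULT_EPS_DET) -> float:
    """ΔL for removing the member with feature vector ``x``; L* = L - ΔL."""
    return delta_loglik_from_p(state, mahalanobis_p(state, x), eps_det=eps_det)


def select_removal(
    state: ClusterState,
    X: np.ndarray,
    *,
    eps_det: float = DEFAULT_EPS_DET,
) -> tuple[int, RemovalStep]:
    """Pick the member whose removal maximally increases L (argmax P).

    Evaluates exactly n candidates.  Ties resolve to the smallest member
    index (member indices are kept sorted, and argmax returns the first
    maximum).  Returns the chosen row index together with the
    :class:`RemovalStep` describing P, ΔL and L* for that candidate.
    """
    p_all = mahalanobis_members(state, X)
    pos = int(np.argmax(p_all))
    idx = int(state.member_indices[pos])
    p = float(p_all[pos])
    dl = delta_loglik_from_p(state, p, eps_det=eps_det)
    return idx, RemovalStep(
        removed_index=idx,
        mahal_sq=p,
        delta_loglik=dl,
        loglik_after=state.loglik - dl,
    )


def downdate(
    state: ClusterState,
    X: np.ndarray,
    removed_index: int,
    *,
    min_cluster_size: int = 2,
    eps_det: float = DEFAULT_EPS_DET,
    refactor_every: int = DEFAULT_REFACTOR_EVERY,
) -> ClusterState:
    """Exact removal of one member, updating all sufficient statistics in O(d²).

    μ* and Σ* follow the closed-form downdates; |Σ*| the rank-one determinant
    identity; Σ*⁻¹ a Sherman–Morrison update of the scaled inverse.  Every
    ``refactor_every`` downdates — or whenever the determinant factor falls
    below 1e-8, where the rank-one update loses accuracy — the inverse and
    log-determinant are recomputed from Σ* directly.
    """
    removed_index = int(removed_index)
    pos = np.searchsorted(state.member_indices, removed_index)
    if pos >= state.n or state.member_indices[pos] != removed_index:
        raise InvalidInputError(f"sample {removed_index} is not a member of the cluster")
    if state.n - 1 < min_cluster_size:
        raise InvalidInputError(
            f"removal would shrink the cluster below min_cluster_size={min_cluster_size}"
        )
    n, d = state.n, state.d
    x = X[removed_index]
    u = x - state.mu
    p = float(u @ state.sigma_inv @ u)
    factor = max(1.0 - p / (n - 1), eps_det)

    mu_new = state.mu - u / (n - 1)
    sigma_new = (n / (n - 1)) * state.sigma - (n / (n - 1) ** 2) * np.outer(u, u)
    sigma_new = 0.5 * (sigma_new + sigma_new.T)

    updates = state.updates_since_refactor + 1
    ridge = state.ridge
    if factor < 1e-8 or updates >= refactor_every:
        sigma_new, sigma_inv_new, log_det_new, ridge = _factorize(sigma_new)
        updates = 0
    else:
        # Σ* = A - c uuᵀ with A = n/(n-1) Σ, c = n/(n-1)²; Sherman–Morrison on A.
        a_inv = ((n - 1) / n) * state.sigma_inv
        c = n / (n - 1) ** 2
        w = a_inv @ u
        sigma_inv_new = a_inv + (c / factor) * np.outer(w, w)
        sigma_inv_new = 0.5 * (sigma_inv_new + sigma_inv_new.T)
        log_det_new = state.log_det_sigma + d * math.log(n / (n - 1)) + math.log(factor)

    members = np.delete(state.member_indices, pos)
    return ClusterState(
        member_indices=members,
        n=n - 1,
        d=d,
        mu=mu_new,
        sigma=sigma_new,
        sigma_inv=sigma_inv_new,
        log_det_sigma=log_det_new,
        loglik=gaussian_loglik(n - 1, d, log_det_new),
        ridge=ridge,
        updates_since_refactor=updates,
    )
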