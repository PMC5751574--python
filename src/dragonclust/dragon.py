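"""Divisive maximum-likelihood clustering by one-at-a-time sample removal.

The procedure is top-down and peels one cluster at a time from the active
sample set:

1. Fit a single Gaussian to the active set and compute its likelihood L.
2. Repeatedly remove the sample whose deletion maximally increases L
   (equivalently, the member at the largest squared Mahalanobis distance P
   from the current centre).  Stop when no removal increases L, or when the
   cluster would fall below the minimum size.  The surviving members form
   the candidate cluster χ_s.
3. Refine χ_s: compute the Euclidean distance of every active sample to the
   cluster centroid μ_s, split those 1-D distances into two groups by the
   exact two-cluster 1-D k-means (all sorted splits, minimum within-group
   sum of squares), and keep the low-distance group as the new χ_s.
   Repeat the distance partition a fixed number of times, recomputing μ_s.
4. Remove χ_s from the active set and repeat until the requested number of
   clusters is reached; the final cluster is whatever remains.

The number of clusters, when unknown, is estimated from the total
log-likelihood curve L_t(c) = Σ L_i: successive differences
δL_t(k) = L_t(k+1) − L_t(k) are min-max normalised over k, and the chosen c
is the first k whose normalised gain drops below a threshold τ — the elbow
of the curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import mlcore
from .mlcore import (
    ClusterState,
    InvalidInputError,
    RemovalStep,
    fit_gaussian,
)

logger = logging.getLogger(__name__)


@dataclass
class DragonConfig:
    """Knobs of the divisive clustering run.

    n_clusters:     number of clusters c, or ``"auto"`` to estimate it.
    max_clusters:   largest c searched when auto (C).
    refine_iters:   number of distance-partition refinement passes per cluster.
    tau:            threshold on the normalised likelihood gain for choosing c.
    min_cluster_size: smallest allowed cluster during extraction; ``None``
                    resolves to max(d + 2, 3), the smallest n giving a
                    usable (generically nonsingular) covariance.
    eps_det:        floor on the determinant factor 1 - P/(n-1) before log.
    refactor_every: rank-one downdates between full refactorisations of Σ⁻¹.
    seed:           reserved for randomised refinement variants; the default
                    path is fully deterministic and ignores it.
    """

    n_clusters: int | str = "auto"
    max_clusters: int = 8
    refine_iters: int = 2
    tau: float = 0.10
    min_cluster_size: int | None = None
    eps_det: float = mlcore.DEFAULT_EPS_DET
    refactor_every: int = mlcore.DEFAULT_REFACTOR_EVERY
    seed: int = 0

    def resolved_min_size(self, d: int) -> int:
        if self.min_cluster_size is not None:
            if self.min_cluster_size < 2:
                raise InvalidInputError("min_cluster_size must be >= 2")
            return int(self.min_cluster_size)
        return max(d + 2, 3)


@dataclass
class RemovalTrace:
    """Ordered record of one cluster extraction.

    ``n_evaluations`` counts candidate evaluations spent on scans that ended
    in a removal; extracting a cluster of pre-refinement size n1 from an
    active set of size n costs exactly (1/2)(n − n1)(n + n1 + 1) such
    evaluations.  The scan that certifies the stop (its best, rejected
    candidate) is kept separately in ``stop_candidate``.
    """

    steps: list[RemovalStep] = field(default_factory=list)
    initial_loglik: float = 0.0
    final_loglik: float = 0.0
    n_evaluations: int = 0
    stop_reason: str = ""
    stop_candidate: RemovalStep | None = None


@dataclass
class ClusteringResult:
    """Final labels plus the per-cluster likelihoods and extraction traces."""

    labels: np.ndarray
    cluster_logliks: list[float]
    total_loglik: float
    traces: list[RemovalTrace]
    refinement_reassignments: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_logliks)


@dataclass
class ModelSelectionCurve:
    """Total-likelihood curve over c = 1…C and the elbow-based choice of c."""

    c_values: np.ndarray
    total_logliks: np.ndarray
    dlt_raw: np.ndarray
    dlt_norm: np.ndarray
    chosen_c: int


def _validate_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError("sample matrix must be 2-D (rows = samples)")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("sample matrix contains non-finite entries")
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise InvalidInputError("need at least 2 samples and 1 feature")
    return X


def extract_cluster(
    X: np.ndarray,
    active,
    config: DragonConfig,
) -> tuple[ClusterState, RemovalTrace]:
    """Peel one cluster from ``active`` by likelihood-increasing removals.

    Starts from χ_s = active; while the best single removal strictly
    increases L (ΔL < 0) and the cluster stays above the minimum size, that
    sample is removed.  Returns the state at the likelihood maximum together
    with the full trace; likelihoods along the trace are strictly increasing.
    """
    X = _validate_matrix(X)
    min_size = config.resolved_min_size(X.shape[1])
    active = np.asarray(sorted(int(i) for i in np.asarray(active).ravel()), dtype=np.intp)
    if active.size <= min_size:
        raise InvalidInputError(
            f"active set of size {active.size} is not above min_cluster_size={min_size}"
        )
    if active.size < 2 * min_size:
        logger.warning(
            "active set of size %d is below 2*min_cluster_size=%d; extraction may be degenerate",
            active.size, 2 * min_size,
        )
    state = fit_gaussian(X, active)
    trace = RemovalTrace(initial_loglik=state.loglik)
    while True:
        if state.n <= min_size:
            trace.stop_reason = "min_cluster_size"
            break
        idx, step = mlcore.select_removal(state, X, eps_det=config.eps_det)
        if not step.delta_loglik < 0.0:
            trace.stop_reason = "converged"
            trace.stop_candidate = step
            break
        trace.n_evaluations += state.n
        state = mlcore.downdate(
            state, X, idx,
            min_cluster_size=min_size,
            eps_det=config.eps_det,
            refactor_every=config.refactor_every,
        )
        # record the realised likelihood of the downdated state, which agrees
        # with L - ΔL to rounding but is what later steps actually start from
        trace.steps.append(
            RemovalStep(
                removed_index=idx,
                mahal_sq=step.mahal_sq,
                delta_loglik=step.delta_loglik,
                loglik_after=state.loglik,
            )
        )
    trace.final_loglik = state.loglik
    return state, trace


def two_means_split_1d(values: np.ndarray) -> np.ndarray:
    """Exact two-cluster 1-D k-means: boolean mask of the low-value group.

    Scans all n − 1 splits of the sorted values and keeps the one minimising
    the within-group sum of squares (the global 2-means optimum in one
    dimension).  Returns an all-True mask when every value is identical
    (no split possible).
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 2 or np.all(values == values[0]):
        return np.ones(n, dtype=bool)
    order = np.argsort(values, kind="stable")
    s = values[order]
    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    total_sum, total_sq = csum[-1], csq[-1]
    k = np.arange(1, n)  # size of the low group
    wcss_low = csq[:-1] - csum[:-1] ** 2 / k
    wcss_high = (total_sq - csq[:-1]) - (total_sum - csum[:-1]) ** 2 / (n - k)
    best = int(np.argmin(wcss_low + wcss_high))
    mask = np.zeros(n, dtype=bool)
    mask[order[: best + 1]] = True
    return mask


def refine_cluster(
    X: np.ndarray,
    active,
    mu_s: np.ndarray,
    config: DragonConfig | None = None,
) -> np.ndarray:
    """One distance-partition pass: keep the active samples nearest μ_s.

    Euclidean distances of all active samples to μ_s are split into two
    groups by the exact 1-D 2-means; the group with the lower mean distance
    becomes the refined cluster.  If all distances are identical the active
    set is returned unchanged (logged).
    """
    X = _validate_matrix(X)
    active = np.asarray(sorted(int(i) for i in np.asarray(active).ravel()), dtype=np.intp)
    if active.size < 2:
        raise InvalidInputError("refinement needs at least 2 active samples")
    mu_s = np.asarray(mu_s, dtype=float).ravel()
    if mu_s.size != X.shape[1]:
        raise InvalidInputError("centroid dimension mismatch")
    dist = np.linalg.norm(X[active] - mu_s, axis=1)
    mask = two_means_split_1d(dist)
    if mask.all():
        logger.warning("all distances to the centroid identical; no refinement split")
        return active.copy()
    return active[mask]


def _refine(X, active, state, config: DragonConfig) -> np.ndarray:
    """Iterate the distance partition, recomputing μ_s between passes."""
    chi_s = state.member_indices
    mu_s = state.mu
    for _ in range(config.refine_iters):
        chi_s = refine_cluster(X, active, mu_s, config)
        mu_s = X[chi_s].mean(axis=0)
    return chi_s


def dragon_fit(X: np.ndarray, config: DragonConfig | None = None) -> ClusteringResult:
    """Full divisive clustering into ``config.n_clusters`` clusters.

    Clusters are peeled one at a time (extraction + refinement); the final
    cluster is the remaining active set.  Per-cluster likelihoods L_i are
    computed on the final memberships and summed into the total L_t.
    Label ids follow extraction order, starting at 0.
    """
    config = config or DragonConfig()
    X = _validate_matrix(X)
    n, d = X.shape
    min_size = config.resolved_min_size(d)
    if config.n_clusters == "auto":
        curve = estimate_c(X, config)
        c = curve.chosen_c
    else:
        c = int(config.n_clusters)
    if c < 1:
        raise InvalidInputError("n_clusters must be >= 1")
    if n < c * min_size:
        raise InvalidInputError(
            f"{n} samples cannot form {c} clusters of at least {min_size}; "
            f"at most {n // min_size} clusters are achievable"
        )

    labels = np.full(n, -1, dtype=int)
    active = np.arange(n, dtype=np.intp)
    traces: list[RemovalTrace] = []
    reassignments: list[int] = []
    for k in range(c - 1):
        if active.size <= min_size:
            raise InvalidInputError(
                f"active set exhausted after {k} clusters; "
                f"only {k + 1} clusters are achievable"
            )
        state, trace = extract_cluster(X, active, config)
        traces.append(trace)
        if state.n == active.size:
            raise InvalidInputError(
                f"the remaining {active.size} samples are already at their likelihood "
                f"maximum; only {k + 1} clusters are achievable"
            )
        chi_s = _refine(X, active, state, config)
        moved = int(np.setdiff1d(chi_s, state.member_indices).size
                    + np.setdiff1d(state.member_indices, chi_s).size)
        if chi_s.size < min_size or chi_s.size == active.size:
            logger.warning(
                "refinement produced a degenerate split (size %d of %d); "
                "keeping the extracted set", chi_s.size, active.size,
            )
            chi_s = state.member_indices
            moved = 0
        reassignments.append(moved)
        labels[chi_s] = k
        active = np.setdiff1d(active, chi_s, assume_unique=True)
        if active.size < max(min_size, 2) and k < c - 2:
            raise InvalidInputError(
                f"active set fell below min_cluster_size; only {k + 2} clusters are achievable"
            )
    if active.size < 2:
        raise InvalidInputError("final cluster has fewer than 2 samples")
    labels[active] = c - 1

    cluster_logliks = []
    for k in range(c):
        members = np.flatnonzero(labels == k)
        st = fit_gaussian(X, members)
        cluster_logliks.append(st.loglik)
    return ClusteringResult(
        labels=labels,
        cluster_logliks=cluster_logliks,
        total_loglik=float(sum(cluster_logliks)),
        traces=traces,
        refinement_reassignments=reassignments,
    )


def total_likelihood(result: ClusteringResult) -> float:
    """Total log-likelihood L_t = Σ_i L_i across the final clusters."""
    return float(sum(result.cluster_logliks))


def normalize_dlt(dlt_raw: np.ndarray) -> np.ndarray:
    """Min-max normalise the successive likelihood gains onto [0, 1]."""
    dlt_raw = np.asarray(dlt_raw, dtype=float)
    lo, hi = dlt_raw.min(), dlt_raw.max()
    if hi == lo:
        logger.warning("constant likelihood gains; normalised curve set to zeros")
        return np.zeros_like(dlt_raw)
    return (dlt_raw - lo) / (hi - lo)


def estimate_c(X: np.ndarray, config: DragonConfig | None = None) -> ModelSelectionCurve:
    """Estimate the number of clusters from the total-likelihood curve.

    Runs the full clustering for c = 1…C, forms δL_t(k) = L_t(k+1) − L_t(k),
    min-max normalises it, and picks the smallest k whose normalised gain
    falls below ``config.tau``; if none does, C is returned with a warning.
    Infeasible values of c truncate the search (with a warning).
    """
    config = config or DragonConfig()
    X = _validate_matrix(X)
    if config.max_clusters < 2:
        raise InvalidInputError("max_clusters must be >= 2")
    if config.n_clusters != "auto" and int(config.n_clusters) > config.max_clusters:
        raise InvalidInputError("n_clusters exceeds max_clusters")
    lts: list[float] = []
    for c in range(1, config.max_clusters + 1):
        cfg = DragonConfig(**{**config.__dict__, "n_clusters": c})
        try:
            lts.append(dragon_fit(X, cfg).total_loglik)
        except InvalidInputError as exc:
            logger.warning("c=%d infeasible (%s); truncating the search", c, exc)
            break
    C = len(lts)
    if C < 2:
        raise InvalidInputError("fewer than 2 feasible cluster counts; cannot estimate c")
    lt = np.asarray(lts)
    dlt_raw = np.diff(lt)
    dlt_norm = normalize_dlt(dlt_raw)
    below = np.flatnonzero(dlt_norm < config.tau)
    if below.size:
        chosen = int(below[0]) + 1
    else:
        logger.warning("no normalised gain fell below tau=%.3g; choosing C=%d", config.tau, C)
        chosen = C
    return ModelSelectionCurve(
        c_values=np.arange(1, C + 1),
        total_logliks=lt,
        dlt_raw=dlt_raw,
        dlt_norm=dlt_norm,
        chosen_c=chosen,
    )
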