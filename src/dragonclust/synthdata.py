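"""Seeded Gaussian-mixture generators mirroring the synthetic benchmark design.

The benchmark draws 400 samples from 4 spherical Gaussian clusters, with the
dimensionality swept over a range and the whole experiment repeated over 20
random seeds.  Cluster centres sit on a deterministic integer grid embedded in
the first few coordinates and scaled so that adjacent centres are a fixed
number of within-cluster standard deviations apart; the ``separation``
parameter therefore directly controls how hard the problem is.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dragon import DragonConfig, dragon_fit, estimate_c
from .evaluation import matched_accuracy
from .mlcore import InvalidInputError


@dataclass(frozen=True)
class SyntheticSpec:
    """Mixture definition: dimension, cluster layout, spread and seed.

    ``separation`` is the distance between adjacent cluster centres in units
    of the within-cluster standard deviation sqrt(covariance_scale); 8 gives
    well-separated clusters, 0 collapses all components onto one another.
    """

    d: int = 2
    n_clusters: int = 4
    n_per_cluster: int = 100
    separation: float = 8.0
    covariance_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.d < 1 or self.n_clusters < 1 or self.n_per_cluster < 1:
            raise InvalidInputError("d, n_clusters and n_per_cluster must be positive")
        if self.separation < 0 or self.covariance_scale <= 0:
            raise InvalidInputError("separation must be >= 0 and covariance_scale > 0")


def cluster_centers(spec: SyntheticSpec) -> np.ndarray:
    """Deterministic centres: integer grid vertices in the leading coordinates.

    Uses the first min(d, n_clusters) coordinates; grid vertices are scaled
    by separation × sqrt(covariance_scale), so every pair of centres is at
    least that far apart.
    """
    d_used = min(spec.d, spec.n_clusters)
    side = math.ceil(spec.n_clusters ** (1.0 / d_used))
    # lexicographic vertices of the smallest cube that holds n_clusters points;
    # for 4 clusters in d >= 2 this is the corners of a square
    pts = list(itertools.islice(
        itertools.product(range(side), repeat=d_used), spec.n_clusters))
    centers = np.zeros((spec.n_clusters, spec.d))
    scale = spec.separation * math.sqrt(spec.covariance_scale)
    centers[:, :d_used] = np.asarray(pts, dtype=float) * scale
    return centers


def make_gaussian_mixture(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw the mixture: (n_clusters × n_per_cluster) × d matrix plus labels.

    Samples are spherical Gaussians around the deterministic centres; rows
    are shuffled with the seed so cluster membership is not encoded in row
    order.  The same spec always produces bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    centers = cluster_centers(spec)
    sd = math.sqrt(spec.covariance_scale)
    blocks, labels = [], []
    for k in range(spec.n_clusters):
        blocks.append(centers[k] + sd * rng.standard_normal((spec.n_per_cluster, spec.d)))
        labels.append(np.full(spec.n_per_cluster, k))
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    perm = rng.permutation(X.shape[0])
    return X[perm], y[perm]


def replicate_experiment(
    d_values,
    n_seeds: int,
    config: DragonConfig | None = None,
    *,
    spec: SyntheticSpec | None = None,
    estimate: bool = False,
) -> pd.DataFrame:
    """Repeat the benchmark over dimensions and seeds; one row per (d, seed).

    For each cell a fresh 4-cluster mixture is generated, the divisive
    clustering is run with the true c, and the matched accuracy recorded.
    With ``estimate=True`` the cluster count is additionally estimated from
    the likelihood curve and reported as ``chosen_c`` (slower: C full runs
    per cell); otherwise ``chosen_c`` is left as pandas NA.
    """
    config = config or DragonConfig()
    base = spec or SyntheticSpec()
    rows = []
    for d in d_values:
        for seed in range(n_seeds):
            cell = SyntheticSpec(
                d=int(d),
                n_clusters=base.n_clusters,
                n_per_cluster=base.n_per_cluster,
                separation=base.separation,
                covariance_scale=base.covariance_scale,
                seed=int(seed),
            )
            X, y = make_gaussian_mixture(cell)
            cfg = DragonConfig(**{**config.__dict__, "n_clusters": cell.n_clusters})
            result = dragon_fit(X, cfg)
            acc = matched_accuracy(y, result.labels).matched_accuracy
            chosen = pd.NA
            if estimate:
                chosen = estimate_c(X, DragonConfig(
                    **{**config.__dict__, "n_clusters": "auto"})).chosen_c
            rows.append({"d": int(d), "seed": int(seed),
                         "accuracy": acc, "chosen_c": chosen})
    return pd.DataFrame(rows)
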