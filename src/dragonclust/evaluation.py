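"""Scoring clusterings against reference labels, and chi-squared gene ranking.

Clustering accuracy is the fraction of samples correctly assigned under the
best one-to-one mapping between predicted clusters and true classes (solved
as an assignment problem on the confusion matrix).  The Rand index counts
sample pairs on which two partitions agree.  The chi-squared ranker scores
each feature by the association between its equal-width-binned values and the
class labels — the standard filter used to pick the top-d genes before
clustering expression data at low dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2_contingency
from sklearn.metrics import rand_score

from .mlcore import InvalidInputError


@dataclass
class AccuracyReport:
    """Confusion matrix, optimal matching and the derived agreement scores."""

    confusion: np.ndarray          # true classes × predicted clusters
    matched_accuracy: float        # in [0, 1]
    rand_index: float              # in [0, 1]
    matching: dict[int, int]       # predicted cluster id -> matched true class id

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "matched_accuracy": self.matched_accuracy,
            "rand_index": self.rand_index,
            "matching": {int(k): int(v) for k, v in self.matching.items()},
        }


def _encode(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).ravel()
    uniq, codes = np.unique(labels, return_inverse=True)
    return uniq, codes


def matched_accuracy(true_labels, pred_labels) -> AccuracyReport:
    """Clustering accuracy under the optimal one-to-one cluster/class matching.

    The confusion matrix is padded square with empty classes when the two
    sides have different numbers of groups, and the matching maximising the
    total matched count is found by the Hungarian method.
    """
    true_labels = np.asarray(true_labels).ravel()
    pred_labels = np.asarray(pred_labels).ravel()
    if true_labels.size == 0 or pred_labels.size == 0:
        raise InvalidInputError("label vectors must be non-empty")
    if true_labels.size != pred_labels.size:
        raise InvalidInputError("label vectors must have equal length")
    true_ids, t = _encode(true_labels)
    pred_ids, p = _encode(pred_labels)
    n_true, n_pred = true_ids.size, pred_ids.size
    side = max(n_true, n_pred)
    confusion = np.zeros((side, side), dtype=int)
    np.add.at(confusion, (t, p), 1)
    row, col = linear_sum_assignment(confusion, maximize=True)
    matched = int(confusion[row, col].sum())
    matching = {int(c): int(r) for r, c in zip(row, col) if c < n_pred and r < n_true}
    return AccuracyReport(
        confusion=confusion[:n_true, :n_pred],
        matched_accuracy=matched / true_labels.size,
        rand_index=rand_index(true_labels, pred_labels),
        matching=matching,
    )


def rand_index(true_labels, pred_labels) -> float:
    """Fraction of sample pairs co-clustered in both partitions or in neither."""
    true_labels = np.asarray(true_labels).ravel()
    pred_labels = np.asarray(pred_labels).ravel()
    if true_labels.size != pred_labels.size or true_labels.size < 2:
        raise InvalidInputError("need two equal-length label vectors with n >= 2")
    return float(rand_score(true_labels, pred_labels))


def chi2_rank_features(
    X: np.ndarray,
    class_labels,
    n_bins: int = 10,
) -> list[tuple[int, float]]:
    """Rank features by the chi-squared statistic of binned value vs class.

    Each feature is discretised into ``n_bins`` equal-width bins over its
    observed range; the chi-squared statistic of the resulting bin × class
    contingency table is its score.  Constant features score 0 by convention.
    Returns (feature index, score) pairs sorted by descending score, ties
    broken by the smaller index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError("sample matrix must be 2-D (rows = samples)")
    y = np.asarray(class_labels).ravel()
    if y.size != X.shape[0]:
        raise InvalidInputError("class label vector length must match sample count")
    if n_bins < 2:
        raise InvalidInputError("n_bins must be >= 2")
    _, codes = _encode(y)
    n_classes = codes.max() + 1
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.clip(np.searchsorted(edges, col, side="right") - 1, 0, n_bins - 1)
        table = np.zeros((n_bins, n_classes), dtype=int)
        np.add.at(table, (bins, codes), 1)
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        scores[j] = chi2_contingency(table, correction=False).statistic
    order = np.argsort(-scores, kind="stable")
    return [(int(j), float(scores[j])) for j in order]
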