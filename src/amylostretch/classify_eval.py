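"""Nearest-neighbor / random-forest classifiers and jackknife evaluation.

Performance is reported as three accuracy rates, in percent:

    acc_pos     = 100 * TP / (TP + FN)      (sensitivity on fibril-forming sites)
    acc_neg     = 100 * TN / (TN + FP)      (specificity on background residues)
    acc_overall = 100 * (TP + TN) / n

A rate whose class is empty is reported as ``None``, never as zero. No class
reweighting is applied by default; with the heavily negative-skewed residue
datasets this means the negative rate dominates the overall rate, which is a
property of the task, not a bug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

if TYPE_CHECKING:  # pragma: no cover
    from .featurization import FeatureMatrix

__all__ = [
    "EvalResult",
    "NearestNeighborClassifier",
    "RandomForest",
    "nn_predict",
    "jackknife",
    "make_kfold_evaluator",
]


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts and the three accuracy rates (percent)."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def acc_pos(self) -> float | None:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else None

    @property
    def acc_neg(self) -> float | None:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else None

    @property
    def acc_overall(self) -> float:
        if self.n == 0:
            raise ValueError("no samples")
        return 100.0 * (self.tp + self.tn) / self.n

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "EvalResult":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("prediction / truth length mismatch")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "acc_pos": self.acc_pos, "acc_neg": self.acc_neg,
            "acc_overall": self.acc_overall,
        }


class NearestNeighborClassifier:
    """1-nearest-neighbor classifier with a deterministic tie rule.

    The predicted label is that of the single nearest training sample under
    Euclidean distance (cosine optionally); exact distance ties resolve to the
    smallest training-row index.
    """

    def __init__(self, metric: str = "euclidean"):
        if metric not in ("euclidean", "cosine"):
            raise ValueError(f"unsupported metric {metric!r}")
        self.metric = metric

    def fit(self, X, y) -> "NearestNeighborClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("training set must be a non-empty 2-d array")
        if len(X) != len(y):
            raise ValueError("X / y length mismatch")
        self._X, self._y = X, y
        return self

    def _distances(self, Q: np.ndarray) -> np.ndarray:
        if self.metric == "euclidean":
            return cdist(Q, self._X, "sqeuclidean")
        return cdist(Q, self._X, "cosine")

    def predict(self, Q) -> np.ndarray:
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        if Q.shape[1] != self._X.shape[1]:
            raise ValueError(
                f"query dimension {Q.shape[1]} != training dimension {self._X.shape[1]}"
            )
        idx = self._distances(Q).argmin(axis=1)  # first minimum: smallest index
        return self._y[idx]


def nn_predict(train: "FeatureMatrix", query) -> int:
    """Label of the nearest training sample for a single query vector."""
    clf = NearestNeighborClassifier().fit(train.values, train.labels)
    return int(clf.predict(np.atleast_2d(query))[0])


class RandomForest:
    """Random forest (bootstrap trees, sqrt-feature subsetting, majority vote).

    A thin deterministic wrapper over scikit-learn's forest; the seed is
    mandatory so repeated runs are reproducible.
    """

    def __init__(self, n_trees: int = 500, seed: int = 0):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self._clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
        )

    def fit(self, X, y) -> "RandomForest":
        self._clf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        return self

    def predict(self, Q) -> np.ndarray:
        return self._clf.predict(np.atleast_2d(np.asarray(Q, dtype=float)))


def jackknife(m: "FeatureMatrix", classifier_factory: Callable[[], object]) -> EvalResult:
    """Leave-one-out evaluation: each sample predicted by a model trained on
    all others; confusion counts aggregated over the n rounds.

    Euclidean nearest-neighbor classifiers take a vectorized path (full
    pairwise distance matrix with the diagonal masked) that is exactly
    equivalent to the generic loop, including the smallest-index tie rule.
    """
    X, y = m.values, m.labels
    n = len(X)
    if n < 2:
        raise ValueError("jackknife needs at least 2 samples")
    probe = classifier_factory()
    if isinstance(probe, NearestNeighborClassifier) and probe.metric == "euclidean":
        D = cdist(X, X, "sqeuclidean")
        np.fill_diagonal(D, np.inf)
        preds = y[D.argmin(axis=1)]
        return EvalResult.from_predictions(y, preds)
    preds = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = classifier_factory()
        clf.fit(X[mask], y[mask])
        preds[i] = clf.predict(X[i : i + 1])[0]
        mask[i] = True
    return EvalResult.from_predictions(y, preds)


def make_kfold_evaluator(n_splits: int = 5, seed: int = 0):
    """Stratified k-fold evaluator with the jackknife's interface.

    A grouped form of leave-one-out: every sample is predicted exactly once by
    a model trained on the other folds. Used where n model refits per point
    (true jackknife) is not affordable, e.g. random-forest IFS curves.
    """

    def evaluate(m: "FeatureMatrix", classifier_factory: Callable[[], object]) -> EvalResult:
        X, y = m.values, m.labels
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        preds = np.empty(len(y), dtype=int)
        for train_idx, test_idx in skf.split(X, y):
            clf = classifier_factory()
            clf.fit(X[train_idx], y[train_idx])
            preds[test_idx] = clf.predict(X[test_idx])
        return EvalResult.from_predictions(y, preds)

    return evaluate
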