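"""MaxRel / mRMR feature ranking and Incremental Feature Selection (IFS).

Features are discretized into three bins at mean ± one standard deviation
(the standard discretization used with mRMR on continuous attributes, with
inclusive boundaries so that binary columns keep their two states). Relevance
and redundancy are plug-in mutual information estimates in bits. The mRMR
variant is MID: each next feature maximizes relevance minus mean redundancy
with the already-selected set. Ties are always broken toward the smallest
column index, so rankings are deterministic and row-order invariant.

IFS walks a ranking, evaluating a classifier on the first k features for each
k (by jackknife or any pluggable evaluator) and records the positive,
negative, and overall accuracy rates; the optimal set is the smallest k
achieving the maximum overall accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .classify_eval import EvalResult
from .featurization import FeatureMatrix, FeatureSchema

__all__ = [
    "discretize",
    "mutual_information",
    "RankedFeatures",
    "maxrel_rank",
    "mrmr_rank",
    "IFSPoint",
    "IFSCurve",
    "ifs_curve",
    "position_contributions",
    "category_enrichment",
    "write_ranking_tsv",
    "write_ifs_tsv",
]


def discretize(column: np.ndarray) -> np.ndarray:
    """Three-bin discretization at mean ± sd (population sd, inclusive bounds).

    Values ``<= mean - sd`` map to 0, ``>= mean + sd`` to 2, the rest to 1.
    Constant columns map to all zeros.
    """
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise ValueError("column must be non-empty")
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return np.zeros(x.size, dtype=np.int8)
    out = np.ones(x.size, dtype=np.int8)
    out[x <= mu - sd] = 0
    out[x >= mu + sd] = 2
    return out


def _codes(v: np.ndarray) -> tuple[np.ndarray, int]:
    uniq, inv = np.unique(v, return_inverse=True)
    return inv, len(uniq)


def _mi_codes(a: np.ndarray, na: int, b: np.ndarray, nb: int) -> float:
    """Plug-in MI (bits) of two already integer-coded vectors."""
    joint = np.bincount(a * nb + b, minlength=na * nb).astype(float)
    joint /= joint.sum()
    pa = joint.reshape(na, nb).sum(axis=1)
    pb = joint.reshape(na, nb).sum(axis=0)
    outer = np.outer(pa, pb).ravel()
    nz = joint > 0
    return float(max(0.0, np.sum(joint[nz] * np.log2(joint[nz] / outer[nz]))))


def mutual_information(x: Sequence[int], y: Sequence[int]) -> float:
    """Plug-in mutual information (in bits) of two discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    (a, na), (b, nb) = _codes(x), _codes(y)
    return _mi_codes(a, na, b, nb)


@dataclass(frozen=True)
class RankedFeatures:
    """A feature ranking: ``order`` is a permutation of the column indices and
    ``relevance[i]`` the MI (bits) of feature ``order[i]`` with the label."""

    order: np.ndarray
    relevance: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(len(self.order))):
            raise ValueError("order must be a permutation of all column indices")


def _discretized(m: FeatureMatrix) -> np.ndarray:
    return np.column_stack([discretize(m.values[:, j]) for j in range(m.n_features)])


def _relevance(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    yc, ny = _codes(y)
    return np.array([_mi_codes(D[:, j], 3, yc, ny) for j in range(D.shape[1])])


def maxrel_rank(m: FeatureMatrix) -> RankedFeatures:
    """Rank features by MI with the label, descending; ties by column index."""
    D = _discretized(m)
    rel = _relevance(D, m.labels)
    order = np.argsort(-rel, kind="stable")
    return RankedFeatures(order, rel[order], "maxrel")


def mrmr_rank(m: FeatureMatrix, top_k: int | None = None) -> RankedFeatures:
    """Greedy MID mRMR ranking.

    The first feature is the MaxRel top; each next feature maximizes
    ``MI(f; y) - mean_{s in selected} MI(f; s)``, ties toward the smallest
    column index. With ``top_k`` the greedy search stops after ``top_k``
    features and the remainder is appended in MaxRel order (the result is
    still a complete permutation).
    """
    d = m.n_features
    steps = d if top_k is None else min(top_k, d)
    D = _discretized(m)
    rel = _relevance(D, m.labels)
    selected: list[int] = []
    remaining = list(range(d))
    red_sum = np.zeros(d)
    for _ in range(steps):
        rem = np.array(remaining)
        if selected:
            scores = rel[rem] - red_sum[rem] / len(selected)
        else:
            scores = rel[rem]
        pick = int(rem[np.argmax(scores)])  # first max -> smallest index on ties
        selected.append(pick)
        remaining.remove(pick)
        if remaining:
            sel_col = D[:, pick]
            for j in remaining:
                red_sum[j] += _mi_codes(D[:, j], 3, sel_col, 3)
    if remaining:
        rem = np.array(remaining)
        tail = rem[np.argsort(-rel[rem], kind="stable")]
        selected.extend(int(j) for j in tail)
    order = np.array(selected)
    return RankedFeatures(order, rel[order], "mrmr")


@dataclass(frozen=True)
class IFSPoint:
    k: int
    acc_pos: float | None
    acc_neg: float | None
    acc_overall: float


@dataclass(frozen=True)
class IFSCurve:
    """Accuracy-vs-feature-count curve; ``best_k`` is the smallest k whose
    overall accuracy attains the curve maximum."""

    points: tuple[IFSPoint, ...]
    best_k: int

    @property
    def best_point(self) -> IFSPoint:
        return next(p for p in self.points if p.k == self.best_k)

    def improving_ks(self) -> list[int]:
        """The k whose overall accuracy strictly exceeds that at k-1 (the
        features "that increase the accuracy"); k=1 counts as improving when
        its accuracy is positive."""
        out = []
        prev = 0.0
        for p in self.points:
            if p.acc_overall > prev:
                out.append(p.k)
            prev = p.acc_overall
        return out


Evaluator = Callable[[FeatureMatrix, Callable[[], object]], EvalResult]


def ifs_curve(
    ranking: RankedFeatures,
    m: FeatureMatrix,
    classifier_factory: Callable[[], object],
    evaluator: Evaluator,
    k_grid: Iterable[int] | None = None,
) -> IFSCurve:
    """Evaluate nested feature sets of increasing size along ``ranking``.

    ``evaluator`` is a cross-validation evaluator such as
    :func:`amylostretch.classify_eval.jackknife`; ``k_grid`` defaults to every
    k from 1 to the feature count.
    """
    if len(ranking.order) != m.n_features:
        raise ValueError("ranking does not cover the matrix columns")
    ks = list(k_grid) if k_grid is not None else list(range(1, m.n_features + 1))
    points = []
    for k in ks:
        sub = m.select_columns(ranking.order[:k])
        res = evaluator(sub, classifier_factory)
        points.append(IFSPoint(k, res.acc_pos, res.acc_neg, res.acc_overall))
    best = max(points, key=lambda p: (p.acc_overall, -p.k))
    return IFSCurve(tuple(points), best.k)


def position_contributions(
    selected: Iterable[int], schema: FeatureSchema
) -> tuple[dict[int, int], float]:
    """Count selected features per window position, plus the mean count.

    Every window position appears in the output (zero when unrepresented);
    counts partition the selection.
    """
    sel = list(selected)
    positions = sorted({e.position for e in schema.entries})
    counts = {p: 0 for p in positions}
    for i in sel:
        counts[schema.entries[i].position] += 1
    mean = len(sel) / len(positions) if positions else 0.0
    return counts, mean


@dataclass(frozen=True)
class CategoryEnrichment:
    count: int
    total: int
    ratio: float
    enriched: bool


def category_enrichment(
    selected: Iterable[int], schema: FeatureSchema, reference_ratio: float
) -> dict[str, CategoryEnrichment]:
    """Per-category selected/total ratios, flagged when above the reference.

    The natural reference is the overall selected fraction
    (``len(selected) / len(schema)``).
    """
    sel = set(selected)
    cats: dict[str, list[int]] = {}
    for i, e in enumerate(schema.entries):
        cats.setdefault(e.category, []).append(i)
    out = {}
    for cat, idx in cats.items():
        count = sum(1 for i in idx if i in sel)
        ratio = count / len(idx)
        out[cat] = CategoryEnrichment(count, len(idx), ratio, ratio > reference_ratio)
    return out


def write_ranking_tsv(
    ranking: RankedFeatures, schema: FeatureSchema, path: str | Path
) -> Path:
    """Export a ranking: rank, column index, window position, attribute,
    category, relevance (bits)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("rank\tfeature_index\tposition\tattribute\tcategory\trelevance_bits\n")
        for rank, (j, rel) in enumerate(zip(ranking.order, ranking.relevance), 1):
            e = schema.entries[j]
            fh.write(f"{rank}\t{j}\t{e.position}\t{e.attribute}\t{e.category}"
                     f"\t{rel:.6g}\n")
    return path


def write_ifs_tsv(curve: IFSCurve, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("k\tacc_pos\tacc_neg\tacc_overall\n")
        for p in curve.points:
            ap = "NA" if p.acc_pos is None else f"{p.acc_pos:.6g}"
            an = "NA" if p.acc_neg is None else f"{p.acc_neg:.6g}"
            fh.write(f"{p.k}\t{ap}\t{an}\t{p.acc_overall:.6g}\n")
    return path
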