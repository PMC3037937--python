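"""Unsupervised sample clustering (UPGMA on Euclidean distances) and the
single-feature partition classifier scored by Fisher's exact test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import AnalysisError
from .dige_io import ExpressionMatrix


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus leaf names."""

    linkage: np.ndarray       # (n-1, 4) scipy format
    leaf_names: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise AnalysisError("merge heights are not non-decreasing")

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.leaf_names[i] for i in order]

    def clusters(self) -> list[frozenset]:
        """Leaf-name sets of every internal node, in merge order."""
        n = len(self.leaf_names)
        sets = {i: frozenset([self.leaf_names[i]]) for i in range(n)}
        out = []
        for k, (i, j, _, _) in enumerate(self.linkage):
            merged = sets[int(i)] | sets[int(j)]
            sets[n + k] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        """Ultrametric Newick string; branch lengths from merge heights/2."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height / 2.0 - node.dist / 2.0
            if node.is_leaf():
                return f"{self.leaf_names[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


def hclust_average(matrix: ExpressionMatrix, features=None) -> Dendrogram:
    """UPGMA (average linkage) on Euclidean distances between sample profiles.

    ``features`` restricts the profile to a feature subset (typically the
    significant ones); default uses all features.
    """
    values = matrix.values if features is None else matrix.values.loc[list(features)]
    X = values.to_numpy().T  # samples x features
    if X.shape[0] < 2:
        raise AnalysisError("clustering needs at least 2 samples")
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="average")
    return Dendrogram(Z, list(values.columns))


@dataclass
class PartitionResult:
    """Best single-feature threshold rule and its Fisher exact p."""

    feature: str
    threshold: float
    high_is_tumor: bool
    confusion: np.ndarray  # rows: true (tumor, benign); cols: pred (tumor, benign)
    accuracy: float
    fisher_p: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        assert self.confusion.shape == (2, 2)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p by the probability-mass rule.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability is <= the observed table's (relative slack
    1e-12). Any zero margin gives p = 1 by convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise AnalysisError("fisher_exact_2x2 needs a non-negative integer 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def single_feature_partition(x_i, labels, feature: str = "") -> PartitionResult:
    """1-D decision stump: midpoint threshold maximizing accuracy.

    Both orientations are considered; accuracy ties are broken toward the
    lower threshold (and, at equal threshold, toward "high predicts tumor").
    """
    x = np.asarray(x_i, dtype=float)
    labels = np.asarray(labels)
    is_tumor = labels == "tumor"
    n_tumor, n_benign = int(is_tumor.sum()), int((~is_tumor).sum())
    if n_tumor < 1 or n_benign < 1:
        raise AnalysisError("partition needs at least 1 sample per class")

    uniq = np.unique(x)
    if len(uniq) == 1:
        majority_tumor = n_tumor >= n_benign
        pred = np.full(len(x), majority_tumor)
        conf = _confusion(is_tumor, pred)
        return PartitionResult(feature, float(uniq[0]), majority_tumor, conf,
                               max(n_tumor, n_benign) / len(x),
                               fisher_exact_2x2(conf), degenerate=True)

    mids = (uniq[:-1] + uniq[1:]) / 2.0
    best = None  # (accuracy, -threshold, high_is_tumor, pred)
    for thr in mids:
        for high_is_tumor in (True, False):
            pred = (x > thr) if high_is_tumor else (x <= thr)
            acc = float((pred == is_tumor).mean())
            key = (acc, -thr, high_is_tumor)
            if best is None or key > best[0]:
                best = (key, thr, high_is_tumor, pred)
    _, thr, high_is_tumor, pred = best
    conf = _confusion(is_tumor, pred)
    return PartitionResult(feature, float(thr), high_is_tumor, conf,
                           float((pred == is_tumor).mean()), fisher_exact_2x2(conf))


def _confusion(is_tumor: np.ndarray, pred_tumor: np.ndarray) -> np.ndarray:
    return np.array([
        [int((is_tumor & pred_tumor).sum()), int((is_tumor & ~pred_tumor).sum())],
        [int((~is_tumor & pred_tumor).sum()), int((~is_tumor & ~pred_tumor).sum())],
    ])


def partition_all_features(matrix: ExpressionMatrix, features=None) -> pd.DataFrame:
    """Run the stump on every (or a subset of) feature, sorted by Fisher p."""
    labels = matrix.labels.to_numpy()
    values = matrix.values if features is None else matrix.values.loc[list(features)]
    rows = []
    for feature, x_i in values.iterrows():
        r = single_feature_partition(x_i.to_numpy(), labels, feature)
        rows.append((feature, r.threshold, r.high_is_tumor, r.accuracy,
                     r.fisher_p, r.degenerate))
    return pd.DataFrame(rows, columns=[
        "feature", "threshold", "high_is_tumor", "accuracy", "fisher_p", "degenerate",
    ]).sort_values(["fisher_p", "feature"], kind="mergesort").set_index("feature")
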