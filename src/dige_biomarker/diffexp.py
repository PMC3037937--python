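"""Spot-wise differential expression: pooled-variance t-tests and the
1.5-fold / p<0.05 significance filter. No multiple-testing correction is
applied; the filter operates on raw p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .dige_io import ExpressionMatrix

ALPHA = 0.05
MIN_FOLD = 1.5


def pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance Student t-test; df = n1 + n2 - 2.

    Zero pooled variance: p = 1 when the means are equal, else p = 0 with
    an infinite statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise AnalysisError("t-test needs at least 2 values per class")
    diff = a.mean() - b.mean()
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def spot_ttest(x_i: np.ndarray, labels) -> tuple[float, float]:
    """t-test of one feature's log values, tumor vs benign."""
    labels = np.asarray(labels)
    x_i = np.asarray(x_i, dtype=float)
    return pooled_ttest(x_i[labels == "tumor"], x_i[labels == "benign"])


def fold_change(x_i: np.ndarray, labels, scale: str = "log") -> float:
    """Tumor/benign fold change on the linear scale.

    ``scale="log"`` (default): 2**(mean_tumor - mean_benign) of the log2
    values, i.e. the ratio of geometric means. ``scale="raw"``: ratio of
    arithmetic means of back-transformed ratios.
    """
    labels = np.asarray(labels)
    x_i = np.asarray(x_i, dtype=float)
    xt, xb = x_i[labels == "tumor"], x_i[labels == "benign"]
    if scale == "log":
        return float(2.0 ** (xt.mean() - xb.mean()))
    if scale == "raw":
        return float((2.0 ** xt).mean() / (2.0 ** xb).mean())
    raise AnalysisError(f"unknown fold-change scale {scale!r}")


def is_significant(fold: float, p: float,
                   alpha: float = ALPHA, min_fold: float = MIN_FOLD) -> bool:
    return (fold >= min_fold or fold <= 1.0 / min_fold) and p < alpha


def run_diffexp(matrix: ExpressionMatrix, scale: str = "log",
                alpha: float = ALPHA, min_fold: float = MIN_FOLD) -> pd.DataFrame:
    """Per-feature t-test, fold change and significance flag."""
    labels = matrix.labels.to_numpy()
    rows = []
    for feature, x_i in matrix.values.iterrows():
        x = x_i.to_numpy()
        t, p = spot_ttest(x, labels)
        fold = fold_change(x, labels, scale=scale)
        rows.append((feature,
                     x[labels == "tumor"].mean(), x[labels == "benign"].mean(),
                     fold, t, p, is_significant(fold, p, alpha, min_fold)))
    return pd.DataFrame(rows, columns=[
        "feature", "mean_tumor", "mean_benign", "fold", "t", "p", "significant",
    ]).set_index("feature")


def significant_spots(results: pd.DataFrame,
                      alpha: float = ALPHA, min_fold: float = MIN_FOLD) -> pd.DataFrame:
    """Features passing the fold + raw-p filter, sorted by p ascending."""
    fold = results["fold"]
    keep = ((fold >= min_fold) | (fold <= 1.0 / min_fold)) & (results["p"] < alpha)
    return results[keep].sort_values("p", kind="mergesort")
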