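"""Two-step outlier-robust PCA and the projection/residual split.

Samples are observations and features variables; each feature is centered
across samples (no variance scaling) and the components come from the SVD of
the centered matrix. Each feature profile x_i then splits exactly into
x_p,i (its part inside the span of the first K score vectors, S3) and
x_r,i (the residual in the complement CS3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .dige_io import ExpressionMatrix
from .diffexp import pooled_ttest

#: robust z-score cutoff for score-space outlier detection
OUTLIER_Z = 3.5
_MAD_SCALE = 1.4826


@dataclass
class PCAModel:
    means: pd.Series                 # per-feature centering means
    loadings: pd.DataFrame           # features x K, orthonormal columns
    scores: pd.DataFrame             # retained samples x K, orthonormal columns
    singular_values: np.ndarray      # first K singular values
    explained_variance_ratio: np.ndarray  # first K fractions of total variance
    retained_samples: list[str]
    outliers: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def sample_coordinates(self) -> pd.DataFrame:
        """PC coordinates of the training samples (scores * singular values)."""
        return self.scores * self.singular_values

    def project(self, x: pd.Series | pd.DataFrame) -> np.ndarray:
        """PC coordinates of new sample profile(s) given over the model's features."""
        if isinstance(x, pd.Series):
            centered = (x - self.means).to_numpy()
        else:
            centered = x.sub(self.means, axis=0).to_numpy()
        return centered.T @ self.loadings.to_numpy() if centered.ndim == 2 \
            else centered @ self.loadings.to_numpy()


def fit_pca(matrix: ExpressionMatrix, k: int = 3) -> PCAModel:
    """PCA of the feature-centered matrix via SVD.

    Sign convention: each score vector's largest-magnitude entry is positive,
    for reproducibility across linear-algebra backends.
    """
    X = matrix.values.to_numpy(dtype=float)
    n_features, n_samples = X.shape
    if k >= min(n_samples, n_features):
        raise AnalysisError(f"k={k} must be < min(n_samples, n_features)")
    if n_samples < k + 1:
        raise AnalysisError("not enough samples for the requested k")
    means = X.mean(axis=1)
    Xc = X - means[:, None]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s ** 2).sum())
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)

    V = Vt[:k].T  # samples x k
    for j in range(k):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]

    samples = matrix.sample_ids
    return PCAModel(
        means=pd.Series(means, index=matrix.values.index, name="mean"),
        loadings=pd.DataFrame(U[:, :k], index=matrix.values.index,
                              columns=[f"PC{j + 1}" for j in range(k)]),
        scores=pd.DataFrame(V, index=samples,
                            columns=[f"PC{j + 1}" for j in range(k)]),
        singular_values=s[:k].copy(),
        explained_variance_ratio=evr,
        retained_samples=list(samples),
    )


def detect_outliers(model: PCAModel, z_cut: float = OUTLIER_Z) -> list[str]:
    """Samples whose robust z-score exceeds ``z_cut`` on any retained component.

    z = |score - median| / (1.4826 * MAD); components with zero MAD are
    skipped, as are components with negligible singular value (they carry
    no expression variance, only numerical noise).
    """
    flagged: set[str] = set()
    sv = model.singular_values
    for j, col in enumerate(model.scores.columns):
        if sv[0] <= 0 or sv[j] <= 1e-8 * sv[0]:
            continue
        s = model.scores[col].to_numpy()
        med = np.median(s)
        dev = np.abs(s - med)
        mad = np.median(dev)
        # scores are unit-norm: MAD at rounding-noise level counts as zero
        if mad <= 1e-9 * max(1.0, dev.max()):
            continue
        z = np.abs(s - med) / (_MAD_SCALE * mad)
        flagged.update(np.asarray(model.scores.index)[z > z_cut])
    return sorted(flagged)


def robust_pca(matrix: ExpressionMatrix, k: int = 3,
               z_cut: float = OUTLIER_Z) -> PCAModel:
    """Two-step PCA: fit, drop score-space outliers, refit once."""
    first = fit_pca(matrix, k)
    outliers = detect_outliers(first, z_cut)
    if not outliers:
        return first
    kept = [s for s in matrix.sample_ids if s not in outliers]
    if len(kept) < k + 1:
        raise AnalysisError("outlier removal leaves too few samples for PCA")
    model = fit_pca(matrix.subset_samples(kept), k)
    model.outliers = outliers
    return model


@dataclass
class Decomposition:
    """Per-feature split x_i = x_p,i + x_r,i over the retained samples."""

    projection: pd.DataFrame  # x_p: feature mean + rank-K part
    residual: pd.DataFrame    # x_r: remainder, centered part orthogonal to S3


def decompose(matrix: ExpressionMatrix, model: PCAModel) -> Decomposition:
    """Split each feature into its S3 projection and CS3 residual.

    x_p,i = mean_i + sum_k (c_i . t_k) t_k with c_i the centered profile;
    x_r,i = x_i - x_p,i. Additivity is exact by construction.
    """
    if list(matrix.values.columns) != model.retained_samples:
        sub = [s for s in matrix.sample_ids if s in set(model.retained_samples)]
        if sub != model.retained_samples:
            raise AnalysisError("matrix samples do not match the model's retained set")
        matrix = matrix.subset_samples(model.retained_samples)
    if list(matrix.values.index) != list(model.means.index):
        raise AnalysisError("matrix features do not match the model")

    X = matrix.values.to_numpy(dtype=float)
    means = model.means.to_numpy()
    V = model.scores.to_numpy()  # samples x k
    C = X - means[:, None]
    proj = means[:, None] + (C @ V) @ V.T
    return Decomposition(
        projection=pd.DataFrame(proj, index=matrix.values.index,
                                columns=matrix.values.columns),
        residual=pd.DataFrame(X - proj, index=matrix.values.index,
                              columns=matrix.values.columns),
    )


def component_ttests(decomp: Decomposition, matrix: ExpressionMatrix) -> pd.DataFrame:
    """Two-sided pooled t-tests per feature on x_i, x_p,i and x_r,i.

    All three tests run on the model's retained samples only.
    """
    samples = list(decomp.projection.columns)
    labels = matrix.labels.loc[samples].to_numpy()
    orig = matrix.values[samples]
    t_mask, b_mask = labels == "tumor", labels == "benign"

    def pvals(df: pd.DataFrame) -> np.ndarray:
        X = df.to_numpy(dtype=float)
        return np.array([pooled_ttest(row[t_mask], row[b_mask])[1] for row in X])

    return pd.DataFrame({
        "p_orig": pvals(orig),
        "p_proj": pvals(decomp.projection),
        "p_resid": pvals(decomp.residual),
    }, index=decomp.projection.index)
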