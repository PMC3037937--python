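"""Logistic classification on the first three principal components:
leave-one-out cross-validation with the PCA refit inside every fold,
tumor-group splitting on the linear predictor, per-PC correlation ranking,
and the random-panel averaging experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import AnalysisError
from .dige_io import ExpressionMatrix
from .diffexp import pooled_ttest
from .pca_split import robust_pca

#: |coefficient| beyond which the ML fit is treated as separated
SEPARATION_COEF = 1e3
#: L2 penalty applied to the slopes in the separation fallback
FALLBACK_RIDGE = 1e-3


def _newton_logit(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                  max_iter: int = 100, tol: float = 1e-10):
    """Newton/IRLS logistic regression; X already carries an intercept column.

    The ridge penalty, when non-zero, is applied to the slopes only.
    Returns (beta, converged).
    """
    n, k = X.shape
    beta = np.zeros(k)
    pen = np.full(k, ridge)
    pen[0] = 0.0
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - pen * beta
        hess = (X * w[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, True
        if np.max(np.abs(beta)) > 1e8:
            return beta, False
    return beta, False


@dataclass
class LogitModel:
    """Fitted logistic model on PC (or proxy) scores."""

    coef: np.ndarray          # [intercept, b1, ..., bK]
    penalized: bool           # separation fallback triggered
    converged: bool
    sample_ids: list[str] = field(default_factory=list)

    def linear_predictor(self, scores: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(scores, dtype=float))
        return self.coef[0] + Z @ self.coef[1:]

    def predict_proba(self, scores: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(scores))


def fit_logit_on_pcs(scores, labels, sample_ids=None) -> LogitModel:
    """Maximum-likelihood logit of class on scores (samples x K).

    Complete or quasi-separation (non-convergence or any |coefficient| above
    1e3) triggers a refit with an L2 penalty of 1e-3 on the slopes; the model
    is flagged ``penalized``.
    """
    Z = np.asarray(scores, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    y = (np.asarray(labels) == "tumor").astype(float)
    if y.min() == y.max():
        raise AnalysisError("logit needs both classes present")
    X = np.column_stack([np.ones(len(y)), Z])
    beta, converged = _newton_logit(X, y)
    penalized = False
    if not converged or np.max(np.abs(beta)) > SEPARATION_COEF:
        beta, converged = _newton_logit(X, y, ridge=FALLBACK_RIDGE)
        penalized = True
    if not np.all(np.isfinite(beta)):
        raise AnalysisError("logit coefficients did not stay finite")
    return LogitModel(beta, penalized, converged,
                      list(sample_ids) if sample_ids is not None else [])


@dataclass
class LoocvResult:
    accuracy: float
    confusion: np.ndarray     # rows: true (tumor, benign); cols: predicted
    probabilities: pd.Series  # per-sample held-out tumor probability
    n_penalized_folds: int = 0


def loocv(matrix: ExpressionMatrix, k: int = 3) -> LoocvResult:
    """Leave-one-out CV of robust PCA (refit per fold) + 3-PC logit.

    The held-out sample never enters centering, PCA or the logit fit; it is
    projected with the training means and loadings and called tumor when its
    predicted probability exceeds 0.5.
    """
    samples = matrix.sample_ids
    labels = matrix.labels
    probs = {}
    n_pen = 0
    for held in samples:
        train_ids = [s for s in samples if s != held]
        train = matrix.subset_samples(train_ids)
        model = robust_pca(train, k)
        coords = model.sample_coordinates().to_numpy()
        fit = fit_logit_on_pcs(coords, labels.loc[model.retained_samples].to_numpy())
        n_pen += int(fit.penalized)
        z = model.project(matrix.values[held])
        probs[held] = float(fit.predict_proba(z)[0])
    probabilities = pd.Series(probs).loc[samples]
    pred_tumor = probabilities > 0.5
    is_tumor = (labels == "tumor").to_numpy()
    pt = pred_tumor.to_numpy()
    confusion = np.array([
        [int((is_tumor & pt).sum()), int((is_tumor & ~pt).sum())],
        [int((~is_tumor & pt).sum()), int((~is_tumor & ~pt).sum())],
    ])
    accuracy = float((pt == is_tumor).mean())
    return LoocvResult(accuracy, confusion, probabilities, n_pen)


# ---------------------------------------------------------------------------
# tumor-group split

@dataclass
class TumorGroups:
    assignments: pd.Series  # tumor sample id -> 1 or 2
    separation: float       # |m1 - m2| / pooled within-group s.d.
    weak: bool

    def group(self, g: int) -> list[str]:
        return list(self.assignments.index[self.assignments == g])


def _kmeans_1d(x: np.ndarray, rng: np.random.Generator, restarts: int = 10):
    """2-means in one dimension, best of ``restarts`` random initializations."""
    best = None
    for _ in range(restarts):
        centers = rng.choice(x, size=2, replace=False)
        for _ in range(100):
            assign = np.abs(x[:, None] - centers[None, :]).argmin(axis=1)
            if len(np.unique(assign)) < 2:
                assign[np.argmax(np.abs(x - centers[assign]))] = 1 - assign.max()
            new = np.array([x[assign == j].mean() for j in (0, 1)])
            if np.allclose(new, centers):
                break
            centers = new
        inertia = float(((x - centers[assign]) ** 2).sum())
        if best is None or inertia < best[0]:
            best = (inertia, assign.copy(), centers.copy())
    return best[1], best[2]


def split_tumor_groups(linear_predictor: pd.Series, labels: pd.Series,
                       seed: int = 0, weak_threshold: float = 1.0) -> TumorGroups:
    """2-means split of the tumor samples on the logit linear predictor.

    Group 1 is the cluster whose mean predictor lies nearer the benign mean.
    The separation statistic is the gap between the clusters at the 2-means
    boundary in units of the pooled within-cluster s.d.; a value below
    ``weak_threshold`` flags the split as weak (2-means always returns two
    clusters, even for unimodal data).
    """
    tumor_ids = [s for s in linear_predictor.index if labels.loc[s] == "tumor"]
    if len(tumor_ids) < 2:
        raise AnalysisError("tumor-group split needs at least 2 tumor samples")
    benign_ids = [s for s in linear_predictor.index if labels.loc[s] == "benign"]
    x = linear_predictor.loc[tumor_ids].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    assign, centers = _kmeans_1d(x, rng)

    benign_mean = linear_predictor.loc[benign_ids].mean() if benign_ids else -np.inf
    near = np.argmin(np.abs(centers - benign_mean))
    groups = np.where(assign == near, 1, 2)

    x1, x2 = x[groups == 1], x[groups == 2]
    n1, n2 = len(x1), len(x2)
    v1 = x1.var(ddof=1) if n1 > 1 else 0.0
    v2 = x2.var(ddof=1) if n2 > 1 else 0.0
    denom = max(n1 + n2 - 2, 1)
    pooled_sd = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / denom)
    # 1-D 2-means clusters are contiguous: the boundary gap measures how
    # bimodal the predictor really is
    if x1.mean() <= x2.mean():
        gap = x2.min() - x1.max()
    else:
        gap = x1.min() - x2.max()
    sep = float(gap / pooled_sd) if pooled_sd > 0 else np.inf
    return TumorGroups(pd.Series(groups, index=tumor_ids, name="group"),
                       sep, sep < weak_threshold)


def tumor_group_diffexp(matrix: ExpressionMatrix, groups: TumorGroups) -> pd.DataFrame:
    """Per-feature two-sided pooled t-test between the two tumor groups.

    Returns log10 p sorted ascending (most significant first).
    """
    g1, g2 = groups.group(1), groups.group(2)
    if not g1 or not g2:
        raise AnalysisError("both tumor groups must be non-empty")
    X1 = matrix.values[g1].to_numpy(dtype=float)
    X2 = matrix.values[g2].to_numpy(dtype=float)
    rows = []
    for i, feature in enumerate(matrix.values.index):
        _, p = pooled_ttest(X1[i], X2[i])
        rows.append((feature, np.log10(p) if p > 0 else -np.inf))
    return pd.DataFrame(rows, columns=["feature", "log10_p"]) \
        .sort_values(["log10_p", "feature"], kind="mergesort").set_index("feature")


# ---------------------------------------------------------------------------
# correlation ranking and panel experiment

def top_correlated(matrix: ExpressionMatrix, model, n: int = 38) -> dict[str, list[str]]:
    """Per PC: the ``n`` features with highest |Pearson r| to the score vector.

    Ties are broken by feature id; zero-variance features get correlation 0.
    """
    if n > matrix.values.shape[0]:
        raise AnalysisError("n exceeds the number of features")
    sub = matrix.subset_samples(model.retained_samples)
    X = sub.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    out: dict[str, list[str]] = {}
    features = np.asarray(sub.values.index)
    for col in model.scores.columns:
        t = model.scores[col].to_numpy()
        tc = t - t.mean()
        tn = np.linalg.norm(tc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc @ tc) / (norms * tn)
        r = np.nan_to_num(r)
        order = sorted(range(len(features)), key=lambda i: (-abs(r[i]), features[i]))
        out[col] = [features[i] for i in order[:n]]
    return out


def odds_ratio(confusion: np.ndarray) -> float:
    """(a*d)/(b*c); +0.5 added to every cell when any cell is zero."""
    c = np.asarray(confusion, dtype=float)
    a, b = c[0, 0], c[0, 1]
    cc, d = c[1, 0], c[1, 1]
    if min(a, b, cc, d) == 0:
        a, b, cc, d = a + 0.5, b + 0.5, cc + 0.5, d + 0.5
    return float((a * d) / (b * cc))


def _loocv_logit_scores(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fast LOOCV of the logit alone on fixed scores; returns probabilities."""
    n = Z.shape[0]
    X = np.column_stack([np.ones(n), Z])
    probs = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        beta, converged = _newton_logit(X[mask], y[mask])
        if not converged or np.max(np.abs(beta)) > SEPARATION_COEF:
            beta, _ = _newton_logit(X[mask], y[mask], ridge=FALLBACK_RIDGE)
        probs[i] = expit(X[i] @ beta)
    return probs


@dataclass
class PanelCurve:
    """Median LOOCV accuracy and odds ratio vs. panel size."""

    table: pd.DataFrame  # columns: size, median_accuracy, median_odds_ratio
    reps: int
    seed: int


def panel_experiment(matrix: ExpressionMatrix, model,
                     sizes=range(1, 26), reps: int = 200, n_top: int = 38,
                     seed: int = 0) -> PanelCurve:
    """Random-panel averaging: replace each PC by the mean centered profile of
    ``s`` features drawn from that PC's top-``n_top`` correlation list, then
    LOOCV a logit on the three proxy scores (the PCA is not refit: the
    proxies stand in for the components by design).

    Each drawn profile is aligned with the sign of its correlation to the
    component before averaging, so anti-correlated features reinforce rather
    than cancel the component they proxy.
    """
    if reps < 1:
        raise AnalysisError("reps must be >= 1")
    tops = top_correlated(matrix, model, n=n_top)
    sub = matrix.subset_samples(model.retained_samples)
    X = sub.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    feat_index = {f: i for i, f in enumerate(sub.values.index)}
    top_idx = {pc: np.array([feat_index[f] for f in feats])
               for pc, feats in tops.items()}
    corr_sign = {}
    for pc in model.scores.columns:
        tc = model.scores[pc].to_numpy()
        tc = tc - tc.mean()
        s = np.sign(Xc @ tc)
        s[s == 0] = 1.0
        corr_sign[pc] = s
    y = (sub.labels.to_numpy() == "tumor").astype(float)

    rng = np.random.default_rng(seed)
    rows = []
    for s in sizes:
        accs, ors = [], []
        for _ in range(reps):
            Z = []
            for pc in model.scores.columns:
                pick = rng.choice(top_idx[pc], size=s, replace=False)
                Z.append((Xc[pick] * corr_sign[pc][pick, None]).mean(axis=0))
            Z = np.column_stack(Z)
            probs = _loocv_logit_scores(Z, y)
            pred = probs > 0.5
            truth = y.astype(bool)
            conf = np.array([
                [int((truth & pred).sum()), int((truth & ~pred).sum())],
                [int((~truth & pred).sum()), int((~truth & ~pred).sum())],
            ])
            accs.append(float((pred == truth).mean()))
            ors.append(odds_ratio(conf))
        rows.append((int(s), float(np.median(accs)), float(np.median(ors))))
    table = pd.DataFrame(rows, columns=["size", "median_accuracy", "median_odds_ratio"])
    return PanelCurve(table, reps=reps, seed=seed)
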