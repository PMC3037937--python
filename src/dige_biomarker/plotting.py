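"""Diagnostic figures emitted by the CLI (score scatter, p-value split,
panel curves, tumor-group boxplot)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np
import pandas as pd


def plot_score_scatter(model, labels: pd.Series, path: str | Path) -> None:
    """3-D scatter of the first three PC coordinates, colored by class."""
    coords = model.sample_coordinates()
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    for cls, color in (("tumor", "red"), ("benign", "blue")):
        ids = [s for s in coords.index if labels.loc[s] == cls]
        sub = coords.loc[ids]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], sub.iloc[:, 2],
                   c=color, label=cls, marker="*")
    ax.set_xlabel("PC1"), ax.set_ylabel("PC2"), ax.set_zlabel("PC3")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pvalue_split(ttests: pd.DataFrame, path: str | Path) -> None:
    """log10 p of projection and residual components vs the original data."""
    x = np.log10(ttests["p_orig"].clip(lower=1e-300))
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(x, np.log10(ttests["p_proj"].clip(lower=1e-300)),
               c="red", s=12, label="projection (S3)")
    ax.scatter(x, np.log10(ttests["p_resid"].clip(lower=1e-300)),
               c="blue", s=12, label="residual (CS3)")
    lim = min(x.min(), -1) - 0.5
    ax.plot([lim, 0], [lim, 0], "k--", lw=0.8)
    ax.set_xlabel("log10 p, original"), ax.set_ylabel("log10 p, component")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_panel_curves(curve, full_accuracy: float, full_or: float,
                      path: str | Path) -> None:
    """Median accuracy and odds ratio vs panel size, with the 3-PC reference."""
    t = curve.table
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].plot(t["size"], t["median_accuracy"], "b-o", ms=3)
    axes[0].axhline(full_accuracy, color="red", ls=":", label="3-PC logit")
    axes[0].set_xlabel("panel size"), axes[0].set_ylabel("median accuracy")
    axes[1].plot(t["size"], t["median_odds_ratio"], "b-o", ms=3)
    axes[1].axhline(full_or, color="red", ls=":")
    axes[1].set_xlabel("panel size"), axes[1].set_ylabel("median odds ratio")
    axes[1].set_yscale("log")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tumor_groups(linear_predictor: pd.Series, labels: pd.Series,
                      groups, path: str | Path) -> None:
    """Boxplots of the logit output per tumor group and for benign samples."""
    data, names = [], []
    for g in (1, 2):
        ids = groups.group(g)
        data.append(linear_predictor.loc[ids].to_numpy())
        names.append(f"tumor group {g}")
    benign = [s for s in linear_predictor.index if labels.loc[s] == "benign"]
    data.append(linear_predictor.loc[benign].to_numpy())
    names.append("benign")
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.boxplot(data, tick_labels=names)
    ax.set_ylabel("logit linear predictor")
    fig.savefig(path, dpi=120)
    plt.close(fig)
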