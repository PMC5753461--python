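"""Figures for screening-performance results.

Layout mirrors the standard presentation of longitudinal screening
comparisons: risk-percentile curves of the four measures plus a per-decile
short-term risk panel, and stacked bars of first-positive timing.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .evaluate import DetectionWindow, decile_risk, performance_curves

__all__ = ["plot_performance_curves", "plot_first_positive"]


def plot_performance_curves(
    scores_by_algorithm: dict[str, pd.DataFrame],
    window: DetectionWindow,
    fpr_target: float = 0.10,
    xlim: tuple[float, float] = (0.8, 1.0),
    path: str | Path | None = None,
):
    """Three-panel comparison: decile risk (top), PPV/NPV (middle),
    TPR/FPR (bottom), each against the risk percentile."""
    fig, axes = plt.subplots(3, 1, figsize=(7, 10), sharex=True)
    colors = plt.cm.tab10(np.linspace(0, 1, 10))
    for i, (name, scores) in enumerate(scores_by_algorithm.items()):
        c = colors[i]
        curves = performance_curves(scores, window)
        dec = decile_risk(scores, window.tau1)
        if len(dec) >= 2:
            cs = CubicSpline(dec["midpoint"], dec["risk"], bc_type="natural")
            grid = np.linspace(dec["midpoint"].min(), dec["midpoint"].max(), 200)
            axes[0].plot(grid, cs(grid), color=c, label=name)
            axes[0].plot(dec["midpoint"], dec["risk"], "o", color=c, ms=4)
        axes[1].plot(curves["percentile"], curves["ppv"], color=c, label=f"{name} PPV")
        axes[1].plot(curves["percentile"], curves["npv"], color=c, ls="--", label=f"{name} NPV")
        axes[2].plot(curves["percentile"], curves["tpr"], color=c, label=f"{name} TPR")
        axes[2].plot(curves["percentile"], curves["fpr"], color=c, ls="--", label=f"{name} FPR")
        at = curves.iloc[(curves["fpr"] - fpr_target).abs().argmin()]
        for ax in axes:
            ax.axvline(at["percentile"], color=c, ls=":", lw=0.8)
    axes[0].set_ylabel(f"risk of HCC within {window.tau1:g} months")
    axes[1].set_ylabel("PPV (solid) / NPV (dashed)")
    axes[2].set_ylabel("TPR (solid) / FPR (dashed)")
    axes[2].set_xlabel("risk percentile")
    axes[2].set_xlim(*xlim)
    for ax in axes:
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_first_positive(timing: pd.DataFrame, path: str | Path | None = None):
    """Stacked bars of the first-positive comparison categories per pair."""
    fig, ax = plt.subplots(figsize=(7, 4))
    labels = [f"{r.algorithm_a}\nvs\n{r.algorithm_b}" for r in timing.itertuples()]
    bottom = np.zeros(len(timing))
    for col, color in (("first_by_a", "#4c72b0"), ("same_visit", "#999999"), ("first_by_b", "#dd8452")):
        vals = timing[col].to_numpy()
        ax.bar(labels, vals, bottom=bottom, label=col.replace("_", " "), color=color)
        bottom += vals
    ax.set_ylabel("fraction of compared HCC cases")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
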