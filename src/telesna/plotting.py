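"""Report figures: null histograms, subsample boxplots, CI-width curves,
node-level caterpillar plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .permutation import NullDistribution


def plot_null_distribution(dist: NullDistribution, path: str | Path) -> None:
    """Histogram of permuted metric values with the observed value marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    vals = np.asarray(dist.null_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    ax.hist(vals, bins=30, color="steelblue", edgecolor="white")
    ax.axvline(dist.observed, color="red", lw=2, label=f"observed = {dist.observed:.3g}")
    ax.set_xlabel(dist.metric)
    ax.set_ylabel("permutations")
    ax.set_title(f"{dist.metric}: p_upper = {dist.p_upper:.4g}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_subsample_boxes(tab: pd.DataFrame, path: str | Path) -> None:
    """Per-metric boxplots of subsampled values across levels."""
    metrics = sorted(tab["metric"].unique())
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 4), squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        sub = tab[tab["metric"] == metric]
        levels = sorted(sub["level"].unique())
        data = [sub.loc[sub["level"] == lv, "value"].dropna().to_numpy() for lv in levels]
        ax.boxplot(data, tick_labels=[f"{lv:.0%}" for lv in levels])
        if "observed" in sub.columns and sub["observed"].notna().any():
            ax.axhline(float(sub["observed"].iloc[0]), color="red", lw=1, ls="--")
        ax.set_title(metric)
        ax.set_xlabel("subsampling level")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ci_width(tab: pd.DataFrame, path: str | Path) -> None:
    """Mean CI width against the number of sampled individuals."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for metric, grp in tab.groupby("metric"):
        grp = grp.sort_values("size")
        ax.plot(grp["size"], grp["mean_width"], marker="o", label=metric)
    ax.set_xlabel("number of individuals")
    ax.set_ylabel("mean 95% CI width")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_correlation_ribbon(summary: pd.DataFrame, path: str | Path) -> None:
    """Mean correlation vs level, with a +/- sd band per metric."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for metric, grp in summary.groupby("metric"):
        grp = grp.sort_values("level")
        ax.plot(grp["level"], grp["mean_r"], marker="o", label=metric)
        sd = grp["sd_r"].fillna(0.0)
        ax.fill_between(grp["level"], grp["mean_r"] - sd, grp["mean_r"] + sd, alpha=0.2)
    ax.axhline(0.7, color="grey", ls=":", lw=1)
    ax.set_xlabel("subsampling level")
    ax.set_ylabel("correlation with full network")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_node_ci_caterpillar(tab: pd.DataFrame, metric: str, path: str | Path) -> None:
    """Node-level CIs sorted by decreasing observed value."""
    sub = tab[tab["metric"] == metric].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(sub)), 4))
    x = np.arange(len(sub))
    lo = np.clip(sub["observed"] - sub["lower"], 0, None)
    hi = np.clip(sub["upper"] - sub["observed"], 0, None)
    ax.errorbar(
        x, sub["observed"], yerr=[lo, hi],
        fmt="o", ms=4, capsize=2, color="steelblue", ecolor="grey",
    )
    ax.set_xticks(x)
    ax.set_xticklabels(sub["node"], rotation=90, fontsize=7)
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
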