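"""Plotting helpers: group time-courses, PCA scatter, correlation heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .cohort import CorrelationMatrix, PCAResult, group_summary  # noqa: E402


def plot_group_timecourse(
    table: pd.DataFrame,
    metric: str,
    out_path: str | Path,
    value_col: str = "percent_change",
) -> Path:
    """Mean +/- SEM time-course per group for one metric."""
    summ = group_summary(table[table["metric"] == metric], value_col=value_col)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for group, sub in summ.groupby("group", observed=True):
        sub = sub.sort_values("session")
        ax.errorbar(sub["session"].astype(str), sub["mean"], yerr=sub["sem"],
                    marker="o", capsize=3, label=str(group))
    ax.set_xlabel("session")
    ax.set_ylabel(f"{metric} ({value_col})")
    ax.axhline(0.0, color="0.7", lw=0.8, zorder=0)
    ax.legend(frameon=False)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_pca(result: PCAResult, labels: pd.Series, out_path: str | Path) -> Path:
    """PC1 vs PC2 scatter colored by a label series aligned to the scores."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for value, idx in labels.groupby(labels).groups.items():
        pts = result.scores.loc[result.scores.index.intersection(idx)]
        ax.scatter(pts["PC1"], pts["PC2"], s=18, label=str(value), alpha=0.8)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.0%})" if len(evr) > 1 else "PC2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_correlation(matrix: CorrelationMatrix, out_path: str | Path) -> Path:
    """Heatmap of Pearson r with significance stars (two-sided p < 0.05)."""
    r = matrix.r
    fig, ax = plt.subplots(figsize=(0.5 * len(r) + 2,) * 2)
    im = ax.imshow(r.to_numpy(), vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(r)), r.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(r)), r.index, fontsize=7)
    for i in range(len(r)):
        for j in range(len(r)):
            if i != j and bool(matrix.significant.iloc[i, j]):
                ax.text(j, i, "*", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Pearson r", shrink=0.8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
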