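"""Matplotlib views of the standard outputs: stacked usage bars, sharing
heatmap, VJ bubble matrix, spectratype histogram, bias scatter.

Each function returns a Figure; callers decide on saving.  Display
truncation of the sharing heatmap is a plotting parameter, not a statistic.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_usage_bars",
    "plot_sharing_heatmap",
    "plot_vj_bubbles",
    "plot_spectratype",
    "plot_bias_scatter",
]


def plot_usage_bars(usage: pd.DataFrame, title: str = "Gene family usage"):
    """Stacked bar chart of family usage; rows = samples, columns = families."""
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(usage)), 4))
    bottom = np.zeros(len(usage))
    for fam in usage.columns:
        ax.bar(usage.index, usage[fam], bottom=bottom, label=fam)
        bottom += usage[fam].to_numpy()
    ax.set_ylabel("fraction of reads")
    ax.set_title(title)
    ax.legend(fontsize=5, ncol=2, loc="center left", bbox_to_anchor=(1, 0.5))
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    return fig


_STATUS_COLOR = {"HEC": 2, "LEC": 1, "absent": 0}


def plot_sharing_heatmap(records: pd.DataFrame, max_rows: int = 50):
    """Heatmap of per-sample HEC/LEC/absent status for the top shared clones."""
    sample_cols = [
        c for c in records.columns if c not in ("cdr3_aa", "n_case_hec", "hec_type")
    ]
    top = records.head(max_rows)
    mat = top[sample_cols].apply(lambda col: col.map(_STATUS_COLOR)).to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(0.4 * len(sample_cols) + 2, 0.18 * len(top) + 1.5))
    cmap = matplotlib.colors.ListedColormap(["lightgray", "mediumseagreen", "orange"])
    ax.imshow(mat, aspect="auto", cmap=cmap, vmin=0, vmax=2)
    ax.set_xticks(range(len(sample_cols)), sample_cols, rotation=90, fontsize=6)
    ax.set_yticks(range(len(top)), top["cdr3_aa"], fontsize=5)
    ax.set_title("shared HECs (orange=HEC, green=LEC, gray=absent)", fontsize=8)
    fig.tight_layout()
    return fig


def plot_vj_bubbles(matrix: pd.DataFrame, title: str = "VJ combination usage"):
    """Bubble matrix: sphere size = read fraction of each VJ combination."""
    fig, ax = plt.subplots(figsize=(6, 5))
    v_idx, j_idx = np.meshgrid(
        range(len(matrix.index)), range(len(matrix.columns)), indexing="ij"
    )
    sizes = matrix.to_numpy() * 2000
    ax.scatter(v_idx.ravel(), j_idx.ravel(), s=sizes.ravel(), alpha=0.6)
    ax.set_xticks(range(len(matrix.index)), matrix.index, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.columns)), matrix.columns, fontsize=7)
    ax.set_xlabel("V family")
    ax.set_ylabel("J family")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_spectratype(hist: pd.Series, title: str = "CDR3 length distribution"):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(hist.index, hist.to_numpy(), width=0.8)
    ax.set_xlabel("CDR3 length (aa)")
    ax.set_ylabel("fraction of reads")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_bias_scatter(series, c1: int, c2: int, estimate=None):
    """Per-clone read counts at two cycle numbers (log-log) with the
    depth-normalization diagonal; annotates k when an estimate is given."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    o1 = series.counts[c1].to_numpy(dtype=float)
    o2 = series.counts[c2].to_numpy(dtype=float)
    keep = (o1 > 0) & (o2 > 0)
    ax.scatter(o1[keep], o2[keep], s=4, alpha=0.3)
    ratio = o2.sum() / o1.sum()
    grid = np.geomspace(max(o1[keep].min(), 1), o1[keep].max(), 50)
    ax.plot(grid, grid * ratio, "k-", lw=1)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(f"reads at {c1} cycles")
    ax.set_ylabel(f"reads at {c2} cycles")
    if estimate is not None:
        ax.set_title(
            f"k={estimate.k:.2f}, per-cycle={estimate.per_cycle_bias:.3f}", fontsize=9
        )
    fig.tight_layout()
    return fig
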