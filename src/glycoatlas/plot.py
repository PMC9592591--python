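"""Heatmap and dendrogram rendering (matplotlib, file export only)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

from .profiling import ClusteringResult, ScaledMatrix
from .quantification import ProfileMatrix

__all__ = ["plot_heatmap", "plot_dendrogram"]


def plot_heatmap(
    matrix: ProfileMatrix | ScaledMatrix,
    path: str | Path,
    cmap: str = "viridis",
    nd_color: str = "lightgrey",
    log_scale: bool = False,
) -> None:
    """Render a samples x glycoforms heatmap with not-detected cells in
    a dedicated mask colour (the atlas heatmaps' grey)."""
    values = matrix.values.to_numpy(dtype=float)
    mask = matrix.mask.to_numpy(dtype=bool)
    display = np.where(mask, values, np.nan)
    if log_scale:
        with np.errstate(divide="ignore"):
            display = np.log10(np.where(display > 0, display, np.nan))
    fig, ax = plt.subplots(
        figsize=(max(6, matrix.values.shape[1] * 0.12),
                 max(4, matrix.values.shape[0] * 0.18))
    )
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad(nd_color)
    im = ax.imshow(display, aspect="auto", cmap=cm, interpolation="nearest")
    ax.set_yticks(range(matrix.values.shape[0]))
    ax.set_yticklabels(matrix.values.index, fontsize=5)
    ax.set_xticks(range(matrix.values.shape[1]))
    ax.set_xticklabels(matrix.values.columns, fontsize=4, rotation=90)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dendrogram(result: ClusteringResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(10, max(4, len(result.labels) * 0.15)))
    hierarchy.dendrogram(
        result.linkage, labels=result.labels, orientation="right", ax=ax,
        leaf_font_size=6,
    )
    ax.set_xlabel(f"merge height ({result.method})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
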