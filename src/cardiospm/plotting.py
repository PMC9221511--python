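"""Thin matplotlib views of pipeline outputs (dendrograms, SPM heatmaps).

Rendering aesthetics are deliberately minimal; all quantitative output lives
in the TSV/JSON files the pipeline writes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_dendrogram(dendrogram, ax=None, **kwargs):
    """Draw a :class:`~cardiospm.clustering.Dendrogram` with scipy's renderer."""
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    hierarchy.dendrogram(
        dendrogram.linkage, labels=dendrogram.labels, ax=ax, **kwargs
    )
    ax.set_ylabel("1 - Spearman (average linkage)")
    return ax


def plot_spm_heatmap(zscores: pd.DataFrame, ax=None, path: str | Path | None = None):
    """Heatmap of z-score normalised SPM values (genes x species-region pairs)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(2, 0.2 * len(zscores))))
    im = ax.imshow(zscores.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(zscores.shape[1]), zscores.columns, rotation=90)
    ax.set_yticks(range(zscores.shape[0]), zscores.index, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="z-scored SPM")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
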