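"""Plot helpers: dispersion curves and similarity heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .model_selection import DispersionCurve, local_minima
from .similarity import SimilarityMatrix

__all__ = ["plot_dispersion_curve", "plot_similarity_matrix"]


def plot_dispersion_curve(curve: DispersionCurve, path: str | Path) -> None:
    """Cluster dispersion versus cluster number, local minima marked."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(curve.c_values, curve.cd_values, "o-", color="tab:blue", ms=4)
    if len(curve.c_values) >= 3:
        for c in local_minima(curve):
            i = curve.c_values.index(c)
            ax.plot(c, curve.cd_values[i], "v", color="tab:red", ms=9)
    ax.set_xlabel("number of clusters c")
    ax.set_ylabel("cluster dispersion")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_similarity_matrix(mat: SimilarityMatrix, path: str | Path) -> None:
    """Heatmap of a cluster-by-cluster similarity matrix."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(mat.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(mat.col_labels)), mat.col_labels, rotation=90)
    ax.set_yticks(range(len(mat.row_labels)), mat.row_labels)
    ax.set_title(f"{mat.mode} similarity ({mat.centering})", fontsize=10)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
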