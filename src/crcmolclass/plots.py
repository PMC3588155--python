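"""Static figures: group-wise KM panel and the two-way mutation heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .clustering import cluster  # noqa: E402
from .survival import KmCurve  # noqa: E402

__all__ = ["km_plot", "mutation_heatmap"]


def km_plot(curves: dict[str, KmCurve], path: str | Path,
            title: str = "Disease-free survival by molecular group") -> None:
    """Step-function KM panel, one line per group."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, c in sorted(curves.items()):
        ax.step(c.times, c.survival, where="post", label=f"group {name}")
    ax.set_xlabel("years")
    ax.set_ylabel("disease-free survival")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def mutation_heatmap(matrix: pd.DataFrame, path: str | Path,
                     metric: str = "hamming", linkage: str = "average") -> None:
    """Two-way clustered heatmap of the binary mutation matrix.

    Tumours on the horizontal axis, alterations on the vertical; altered
    calls red, wild-type blue.
    """
    tumours = cluster(matrix, metric=metric, linkage=linkage)
    features = cluster(matrix.T, metric=metric, linkage=linkage)
    col_order = [matrix.index.get_loc(i) for i in tumours.leaf_order()]
    row_order = [matrix.columns.get_loc(i) for i in features.leaf_order()]
    arr = matrix.to_numpy(dtype=float)[np.ix_(col_order, row_order)].T
    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.imshow(arr, aspect="auto", cmap="bwr", interpolation="nearest",
              vmin=0, vmax=1)
    ax.set_yticks(range(len(row_order)))
    ax.set_yticklabels([matrix.columns[i] for i in row_order], fontsize=8)
    ax.set_xticks([])
    ax.set_xlabel("tumours (clustered)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
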