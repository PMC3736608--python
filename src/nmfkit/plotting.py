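"""Heat-map visualization of NMF clustering and biclustering results."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .factorizations import FactorizationResult
from .mining import assign_clusters

__all__ = ["HeatmapOrdering", "render_heatmap"]


@dataclass
class HeatmapOrdering:
    """Row/column permutations used in the rendered figure."""

    row_order: NDArray[np.int_]
    col_order: NDArray[np.int_]


def render_heatmap(
    X: ArrayLike,
    result: FactorizationResult,
    path,
    labels: ArrayLike | None = None,
    mode: Literal["clustering", "biclustering"] = "clustering",
) -> HeatmapOrdering:
    """Three-panel heat map: data | basis | coefficients.

    Columns of the data panel are reordered by cluster assignment (argmax of
    Y); in biclustering mode the rows are also reordered by their dominant
    factor (argmax of A) so factor-specific features form contiguous blocks.
    Returns the ordering so callers can test or reuse it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = np.asarray(X, dtype=float)
    m, n = X.shape
    col_labels = assign_clusters(np.maximum(result.Y, 0)).labels
    col_order = np.argsort(col_labels, kind="stable")
    if mode == "biclustering":
        row_factor = np.asarray(result.A).argmax(axis=1)
        row_order = np.argsort(row_factor, kind="stable")
    elif mode == "clustering":
        row_order = np.arange(m)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    fig, axes = plt.subplots(
        1, 3, figsize=(10, 4), width_ratios=[3, 1, 2], constrained_layout=True
    )
    axes[0].imshow(
        X[np.ix_(row_order, col_order)], aspect="auto", cmap="viridis",
        interpolation="nearest",
    )
    axes[0].set_title("data")
    axes[1].imshow(
        np.asarray(result.A)[row_order], aspect="auto", cmap="viridis",
        interpolation="nearest",
    )
    axes[1].set_title("basis")
    axes[2].imshow(
        np.asarray(result.Y)[:, col_order], aspect="auto", cmap="viridis",
        interpolation="nearest",
    )
    axes[2].set_title("coefficients")
    for ax in axes:
        ax.set_xticks([])
        ax.set_yticks([])
    if labels is not None:
        labels = np.asarray(labels)
        axes[0].set_xlabel(
            " ".join(str(v) for v in labels[col_order][: min(n, 30)]), fontsize=6
        )
    fig.savefig(path)
    plt.close(fig)
    return HeatmapOrdering(row_order=row_order, col_order=col_order)
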