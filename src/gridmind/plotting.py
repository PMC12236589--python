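"""Matplotlib views of ratemaps, connectivity, training and recall.

All functions take an optional ``ax`` (or create their own figure) and
return the matplotlib Axes, so they compose into panels; ``save``
writes a PNG when given a path.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .maps import Ratemap
from .network import PopulationLayout, RNNParams

__all__ = [
    "plot_ratemap",
    "plot_ratemap_grid",
    "plot_connectivity",
    "plot_loss_history",
    "plot_recall_distances",
]


def _finish(fig, save):
    if save is not None:
        fig.savefig(save, dpi=120, bbox_inches="tight")
        plt.close(fig)


def plot_ratemap(rmap: Ratemap, cell: int, ax=None, save=None):
    """Heatmap of one cell's spatial tuning (cm axes, origin lower-left)."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(3.2, 3))
    else:
        fig = ax.figure
    m = np.where(rmap.valid, rmap.rates[:, :, cell], np.nan)
    im = ax.imshow(
        m.T, origin="lower", cmap="viridis",
        extent=(0, rmap.arena.width, 0, rmap.arena.height),
    )
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_title(f"{rmap.population_tag} cell {cell}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    _finish(fig, save)
    return ax


def plot_ratemap_grid(rmap: Ratemap, cells=None, ncols: int = 4, save=None):
    """Panel of tuning maps for several cells of one population."""
    cells = list(range(min(rmap.n_cells, 8))) if cells is None else list(cells)
    nrows = (len(cells) + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(2.4 * ncols, 2.4 * nrows),
                             squeeze=False)
    for ax in axes.ravel():
        ax.set_axis_off()
    for ax, c in zip(axes.ravel(), cells):
        m = np.where(rmap.valid, rmap.rates[:, :, c], np.nan)
        ax.set_axis_on()
        ax.imshow(m.T, origin="lower", cmap="viridis")
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_title(str(c), fontsize=8)
    _finish(fig, save)
    return axes


def plot_connectivity(params: RNNParams, ax=None, save=None):
    """Signed heatmap of the full recurrent matrix with population blocks."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4.6))
    else:
        fig = ax.figure
    W = params.W
    v = np.percentile(np.abs(W), 99)
    im = ax.imshow(W, cmap="RdBu_r", vmin=-v, vmax=v)
    layout: PopulationLayout = params.layout
    ticks, labels = [], []
    for name, size in layout.sizes.items():
        if not size:
            continue
        sl = layout.slc(name)
        ticks.append((sl.start + sl.stop) / 2)
        labels.append(name)
        for edge in (sl.start, sl.stop):
            ax.axhline(edge - 0.5, color="k", lw=0.4)
            ax.axvline(edge - 0.5, color="k", lw=0.4)
    ax.set_xticks(ticks, labels, rotation=90, fontsize=7)
    ax.set_yticks(ticks, labels, fontsize=7)
    ax.set_title("recurrent connectivity")
    fig.colorbar(im, ax=ax, shrink=0.8)
    _finish(fig, save)
    return ax


def plot_loss_history(results, window: int = 100, ax=None, save=None):
    """Per-step loss components with a moving average."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(4.5, 3))
    else:
        fig = ax.figure
    h = results.loss_history
    for col in ("loss", "loss_gc", "loss_smc"):
        if col in h and np.any(h[col].values):
            ax.plot(h["step"], h[col].rolling(window, min_periods=1).mean(),
                    label=col)
    ax.set_xlabel("optimizer step")
    ax.set_ylabel("MSE (moving average)")
    ax.set_yscale("log")
    ax.legend(fontsize=8)
    _finish(fig, save)
    return ax


def plot_recall_distances(trace, ax=None, save=None):
    """Decoded distance to the cued location per population over a query."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(4.5, 3))
    else:
        fig = ax.figure
    for name, d in trace.distances.items():
        ax.plot(np.arange(1, len(d) + 1), d, label=name)
    ax.set_xlabel("query timestep")
    ax.set_ylabel("distance to cue (cm)")
    ax.legend(fontsize=8)
    _finish(fig, save)
    return ax
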