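"""Quick-look plots for basemaps and likelihood surfaces."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from elementscape.assignment import AssignmentSurface
from elementscape.basemap import Basemap
from elementscape.io_formats import RasterGrid


def _imshow(ax, grid: RasterGrid, values: np.ndarray, **kwargs):
    im = ax.imshow(values, extent=(grid.west, grid.east, grid.south, grid.north),
                   origin="upper", **kwargs)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return im


def plot_basemap(bm: Basemap, path: str | None = None, samples=None):
    """Render the predicted-score surface; optional sample overlay."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    im = _imshow(ax, bm.mu, bm.mu.values, cmap="viridis")
    fig.colorbar(im, ax=ax, label="predicted PC1 score")
    if samples is not None:
        ax.scatter(samples.lons, samples.lats, s=12, c="k", marker=".")
    ax.set_title(f"basemap (sigma = {bm.sigma:.2f})")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_surface(surface: AssignmentSurface, true_location=None,
                 path: str | None = None):
    """Render one individual's likelihood-of-origin surface."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    im = _imshow(ax, surface.grid, surface.grid.values, cmap="magma",
                 vmin=0.0, vmax=1.0)
    fig.colorbar(im, ax=ax, label="likelihood of origin")
    if true_location is not None:
        ax.scatter([true_location[0]], [true_location[1]], s=40, c="w",
                   edgecolors="k", zorder=3)
    ax.set_title(f"y* = {surface.y_star:.2f}")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
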