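"""Basic diagnostic plots: isoscapes, zone maps, BIC curves, zone boxplots."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .geodata import Raster, TRACERS


def plot_raster(raster: Raster, ax=None, title: str = "", cmap: str = "viridis"):
    """Render a raster with plot-local extents in metres."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 8))
    e = raster.grid.extent
    im = ax.imshow(raster.values, origin="lower", cmap=cmap,
                   extent=[e.x_min, e.x_max, e.y_min, e.y_max])
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax, label=raster.units)
    return ax


def plot_zone_map(zonemap, canopies=None, ax=None, title: str = ""):
    """Integer zone raster with optional canopy outlines."""
    ax = plot_raster(zonemap.labels, ax=ax, title=title, cmap="RdYlBu_r")
    if canopies:
        for poly in canopies:
            xs, ys = poly.exterior.xy
            ax.plot(xs, ys, color="white", lw=1.5)
    return ax


def plot_bic_surface(surface, ax=None):
    """BIC vs number of clusters, one line per covariance code."""
    if ax is None:
        _, ax = plt.subplots()
    for code in surface.values.columns:
        ax.plot(surface.values.index, surface.values[code], marker="o",
                ms=3, label=code)
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("BIC")
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_zone_boxplots(stack, zonemap, distance=None, axes=None):
    """Per-zone boxplots of the three tracers (and canopy distance)."""
    zones = zonemap.zone_of_rows(stack)
    zone_ids = sorted(set(zones))
    names = list(TRACERS) + (["distance"] if distance is not None else [])
    if axes is None:
        _, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 4))
    for ax, name in zip(np.atleast_1d(axes), names):
        if name == "distance":
            vals = distance.values.ravel()[stack.cell_index]
        else:
            vals = stack.rows[:, TRACERS.index(name)]
        ax.boxplot([vals[zones == z] for z in zone_ids], tick_labels=zone_ids)
        ax.set_xlabel("zone")
        ax.set_title(name)
    return axes
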