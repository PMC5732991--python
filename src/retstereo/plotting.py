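"""Rendering of topographic density maps in the wholemount-figure style."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .topography import DensityMap


def plot_density_map(dmap: DensityMap, path: str | Path,
                     levels: list[float] | None = None,
                     site_xy: np.ndarray | None = None) -> None:
    """Filled contour map clipped to the outline, with optional site dots."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    x0, x1, y0, y1 = dmap.extent
    gx, gy = np.meshgrid(dmap.xs, dmap.ys)
    filled = ax.contourf(gx, gy, dmap.raster, levels=levels or 12,
                         cmap="viridis")
    ax.contour(gx, gy, dmap.raster, levels=levels or 12,
               colors="k", linewidths=0.3)
    bx, by = dmap.outline.boundary.exterior.xy
    ax.plot(bx, by, "k-", lw=1)
    for h in dmap.outline.holes:
        hx, hy = h.exterior.xy
        ax.fill(hx, hy, color="white", zorder=3)
        ax.plot(hx, hy, "k-", lw=0.8, zorder=4)
    if site_xy is not None and len(site_xy):
        ax.plot(site_xy[:, 0], site_xy[:, 1], "k.", ms=2, zorder=5)
    if dmap.peak is not None:
        ax.plot(dmap.peak[0], dmap.peak[1], "r+", ms=10, zorder=6)
    fig.colorbar(filled, ax=ax, label="cells / mm$^2$")
    ax.set_aspect("equal")
    ax.set_xlabel("temporal  (mm)")
    ax.set_ylabel("dorsal  (mm)")
    ax.set_title(dmap.cell_type)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
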