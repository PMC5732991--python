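"""Topographic density maps and angular fovea localization.

Scattered per-site densities are interpolated onto a regular raster
(piecewise-linear on the Delaunay triangulation of the site centres, with
nearest-site extrapolation between the sites' convex hull and the outline),
masked to the wholemount outline, and searched for their density peak.  The
peak position is converted to angular retinal coordinates by the flat-map
convention that the horizontal and vertical diameters of the retina each
subtend 180 degrees of visual field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .synthetic import RetinaOutline

__all__ = ["DensityMap", "FoveaPosition", "interpolate_map", "sum_cone_maps",
           "find_peak", "fovea_position_deg"]


@dataclass(frozen=True)
class DensityMap:
    """Raster of densities (cells/mm^2) clipped to a retina outline.

    ``raster[j, i]`` is the density at (xs[i], ys[j]); NaN outside the mask.
    """

    raster: np.ndarray
    mask: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    resolution: float
    cell_type: str
    outline: RetinaOutline
    peak: tuple[float, float, float] | None = None
    interpolation: str = "linear-delaunay+nearest-fill"

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return float(self.xs[0]), float(self.xs[-1]), float(self.ys[0]), float(self.ys[-1])


@dataclass(frozen=True)
class FoveaPosition:
    """Fovea position in angular retinal coordinates (degrees)."""

    degrees_dorsal: float
    degrees_temporal: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.degrees_dorsal <= 90.0
                and -90.0 <= self.degrees_temporal <= 90.0):
            raise ValueError("angular coordinates must lie in [-90, 90] degrees")


def interpolate_map(site_xy: np.ndarray, site_density: np.ndarray,
                    outline: RetinaOutline, resolution: float = 0.025,
                    cell_type: str = "all_cones") -> DensityMap:
    """Interpolate scattered site densities onto an outline-clipped raster.

    Linear interpolation on the triangulation of site centres is exact at the
    sites; pixels between the convex hull and the outline take the nearest
    site's value.  Requires at least three non-collinear sites.
    """
    site_xy = np.asarray(site_xy, dtype=float)
    site_density = np.asarray(site_density, dtype=float)
    if len(site_xy) < 3:
        raise ValueError("need at least three counting sites to build a map")
    if np.linalg.matrix_rank(site_xy - site_xy.mean(axis=0)) < 2:
        raise ValueError("counting sites are collinear; cannot triangulate")
    x0, y0, x1, y1 = outline.boundary.bounds
    xs = np.arange(x0, x1 + resolution / 2, resolution)
    ys = np.arange(y0, y1 + resolution / 2, resolution)
    gx, gy = np.meshgrid(xs, ys)
    mask = outline.contains_points(gx.ravel(), gy.ravel()).reshape(gx.shape)
    lin = LinearNDInterpolator(site_xy, site_density)
    near = NearestNDInterpolator(site_xy, site_density)
    values = lin(gx, gy)
    hole = np.isnan(values)
    if hole.any():
        values[hole] = near(gx[hole], gy[hole])
    raster = np.where(mask, values, np.nan)
    m = DensityMap(raster=raster, mask=mask, xs=xs, ys=ys, resolution=resolution,
                   cell_type=cell_type, outline=outline)
    return DensityMap(**{**m.__dict__, "peak": find_peak(m)})


def sum_cone_maps(maps: list[DensityMap]) -> DensityMap:
    """Pixel-wise sum of density maps sharing one raster geometry."""
    if not maps:
        raise ValueError("need at least one map")
    ref = maps[0]
    for m in maps[1:]:
        if m.raster.shape != ref.raster.shape or \
           not np.allclose(m.xs, ref.xs) or not np.allclose(m.ys, ref.ys):
            raise ValueError("maps do not share raster geometry")
    total = np.where(ref.mask, 0.0, np.nan)
    for m in maps:
        total = total + np.nan_to_num(m.raster, nan=0.0) * ref.mask
    total = np.where(ref.mask, total, np.nan)
    out = DensityMap(raster=total, mask=ref.mask, xs=ref.xs, ys=ref.ys,
                     resolution=ref.resolution, cell_type="all_cones",
                     outline=ref.outline)
    return DensityMap(**{**out.__dict__, "peak": find_peak(out)})


def find_peak(dmap: DensityMap) -> tuple[float, float, float]:
    """Location and value of the raster maximum inside the mask.

    Ties are broken toward the smallest y, then smallest x — deterministic for
    constant maps.
    """
    if not dmap.mask.any():
        raise ValueError("empty mask")
    vals = np.where(dmap.mask, dmap.raster, -np.inf)
    peak_val = np.nanmax(vals)
    jj, ii = np.nonzero(vals == peak_val)
    order = np.lexsort((dmap.xs[ii], dmap.ys[jj]))
    j, i = jj[order[0]], ii[order[0]]
    return float(dmap.xs[i]), float(dmap.ys[j]), float(peak_val)


def fovea_position_deg(peak_xy: tuple[float, float],
                       outline: RetinaOutline) -> FoveaPosition:
    """Angular position of the fovea, the retinal diameters spanning 180 degrees.

    Offsets are measured from the centre of the boundary's bounding box;
    degrees_temporal = 90 * dx / half_width (sign flipped for right eyes, whose
    temporal direction is -x), degrees_dorsal = 90 * dy / half_height.
    """
    x0, y0, x1, y1 = outline.boundary.bounds
    half_w = (x1 - x0) / 2.0
    half_h = (y1 - y0) / 2.0
    if half_w <= 0 or half_h <= 0:
        raise ValueError("degenerate outline")
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    px, py = peak_xy
    if not (x0 <= px <= x1 and y0 <= py <= y1):
        raise ValueError("peak lies outside the outline bounding box")
    sign = 1.0 if outline.eye_side == "left" else -1.0
    return FoveaPosition(degrees_dorsal=90.0 * (py - cy) / half_h,
                         degrees_temporal=sign * 90.0 * (px - cx) / half_w)
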