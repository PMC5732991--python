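"""Synthetic retinal wholemounts with known ground truth.

Generates flattened, hemi-elliptical retina outlines (with an optic-disk hole
and a falciform-process gap), smooth per-cell-type density fields featuring a
dorso-temporal gradient and a Gaussian foveal peak, point patterns drawn from
those fields by inhomogeneous-Poisson thinning, regular cone mosaics (the 2:1
square and 4:1 "lucky-clover" patterns of teleost retinas), and region-wise
post-staining shrinkage distortion.

Coordinate convention: mm units, origin at the centroid of the outline's
bounding box, +x temporal and +y dorsal for a LEFT eye; right-eye geometry is
mirrored about the y-axis on construction.

A twin-cone record represents one twin pair (two members); a triple-cone
record represents three joined members.  Densities are per-record unless
stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon
from shapely.affinity import scale as shp_scale, translate as shp_translate

__all__ = [
    "CELL_TYPES",
    "RetinaOutline",
    "DensityField",
    "CellMap",
    "MosaicSpec",
    "ShrinkageSpec",
    "make_outline",
    "eval_density",
    "sample_point_process",
    "lay_mosaic",
    "apply_shrinkage",
    "quadrant_regions",
]

CELL_TYPES = ("single_cone", "twin_cone", "triple_cone", "rod", "rgc", "amacrine_glia")

_ELLIPSE_SEGMENTS = 256  # boundary vertices for polygonal ellipses/circles


@dataclass(frozen=True)
class RetinaOutline:
    """Flattened retina outline: boundary polygon minus holes, in mm.

    ``boundary`` excludes nothing; ``holes`` (optic disk, falciform gap) are
    subtracted to form the usable tissue polygon.  ``axes`` records the
    antero-posterior and dorso-ventral diameters of the source eye.
    """

    boundary: Polygon
    holes: tuple[Polygon, ...]
    eye_side: str
    axes: tuple[float, float]

    def __post_init__(self) -> None:
        if self.eye_side not in ("left", "right"):
            raise ValueError("eye_side must be 'left' or 'right'")
        if not self.boundary.is_simple or not self.boundary.is_valid:
            raise ValueError("boundary must be a simple, valid polygon")
        for h in self.holes:
            if not self.boundary.contains(h):
                raise ValueError("every hole must lie strictly inside the boundary")
        if self.usable_polygon.area <= 0:
            raise ValueError("usable area must be positive")
        if any(a <= 0 for a in self.axes):
            raise ValueError("axes must be positive")

    @property
    def usable_polygon(self):
        poly = self.boundary
        for h in self.holes:
            poly = poly.difference(h)
        return poly

    @property
    def usable_area(self) -> float:
        return self.usable_polygon.area

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-usable-tissue test (boundary minus holes)."""
        inside = shapely.contains_xy(self.boundary, x, y)
        for h in self.holes:
            inside &= ~shapely.contains_xy(h, x, y)
        return inside


@dataclass(frozen=True)
class DensityField:
    """Parametric cell-density surface (cells/mm^2).

    value(x, y) = trend + sum of Gaussian peak bumps + patch plateaus, floored
    at zero, where trend = base + gradient . (x, y).  A peak's ``peak_value``
    is the field value AT its center: the bump amplitude is
    ``peak_value - trend(center)`` (clamped at 0), so stated foveal peak
    densities are reproduced exactly at the peak.  ``patches`` add a constant
    inside a polygon (used for types confined to a patch, e.g. triple cones).
    ``suppression_masks`` multiply the field by ``1 - exp(-r^2/(2 sigma^2))``
    around a center — used to remove rods from the foveal area.
    """

    base: float = 0.0
    gradient_vector: tuple[float, float] = (0.0, 0.0)
    peaks: tuple[tuple[tuple[float, float], float, float], ...] = ()
    patches: tuple[tuple[Polygon, float], ...] = ()
    suppression_masks: tuple[tuple[tuple[float, float], float], ...] = ()
    floor_at_zero: bool = True

    def __call__(self, x, y):
        return eval_density(self, x, y)

    def upper_bound(self, bounds: tuple[float, float, float, float]) -> float:
        """Supremum of the field over a bounding box (for Poisson thinning)."""
        x0, y0, x1, y1 = bounds
        gx, gy = self.gradient_vector
        corners = [self.base + gx * x + gy * y
                   for x in (x0, x1) for y in (y0, y1)]
        bound = max(max(corners), 0.0)
        for (cx, cy), peak_value, _sigma in self.peaks:
            trend_c = self.base + gx * cx + gy * cy
            bound += max(peak_value - trend_c, 0.0)
        for _poly, value in self.patches:
            bound += max(value, 0.0)
        return bound


def eval_density(field: DensityField, x, y):
    """Evaluate a DensityField at (x, y); accepts scalars or arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gx, gy = field.gradient_vector
    val = field.base + gx * x + gy * y
    for (cx, cy), peak_value, sigma in field.peaks:
        trend_c = field.base + gx * cx + gy * cy
        amp = max(peak_value - trend_c, 0.0)
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        val = val + amp * np.exp(-r2 / (2.0 * sigma ** 2))
    for poly, value in field.patches:
        inside = shapely.contains_xy(poly, np.atleast_1d(x), np.atleast_1d(y))
        val = val + value * inside.reshape(np.shape(val))
    for (cx, cy), sigma in field.suppression_masks:
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        val = val * (1.0 - np.exp(-r2 / (2.0 * sigma ** 2)))
    if field.floor_at_zero:
        val = np.maximum(val, 0.0)
    return val if val.ndim else float(val)


@dataclass(frozen=True)
class CellMap:
    """Typed cell positions (mm) inside a retina outline."""

    x: np.ndarray
    y: np.ndarray
    cell_type: np.ndarray  # dtype=object/str, values from CELL_TYPES
    outline: RetinaOutline
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.x)
        if len(self.y) != n or len(self.cell_type) != n:
            raise ValueError("x, y and cell_type must have equal length")
        unknown = set(np.unique(self.cell_type)) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.x)

    def of_type(self, cell_type: str) -> "CellMap":
        m = self.cell_type == cell_type
        return CellMap(self.x[m], self.y[m], self.cell_type[m], self.outline, self.seed)

    @staticmethod
    def concat(maps: list["CellMap"]) -> "CellMap":
        if not maps:
            raise ValueError("need at least one CellMap")
        return CellMap(
            np.concatenate([m.x for m in maps]),
            np.concatenate([m.y for m in maps]),
            np.concatenate([m.cell_type for m in maps]),
            maps[0].outline,
            maps[0].seed,
        )


@dataclass(frozen=True)
class MosaicSpec:
    """Regular cone-mosaic unit cell.

    square_2to1: one single cone at the lattice node, two twin cones on the
    half-edge positions -> exact 2:1 twin:single record ratio.
    clover_4to1 / clover_skewed: one central single surrounded by four
    unshared twins -> exact 4:1; the skewed variant shears the lattice.
    triple_random: uniform scatter of triples at intensity 1/pitch^2.
    """

    pattern: str
    pitch: float
    shear: float = 0.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.pattern not in ("square_2to1", "clover_4to1", "clover_skewed",
                                "triple_random"):
            raise ValueError(f"unknown mosaic pattern: {self.pattern!r}")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


@dataclass(frozen=True)
class ShrinkageSpec:
    """Region-wise isotropic linear shrinkage, applied about region centroids.

    ``regions`` must tile the outline's usable area (areal coverage within
    1e-6 relative); linear_scale in (0, 1] shrinks post-staining tissue.
    """

    regions: tuple[tuple[Polygon, float], ...]
    reference: str = "pre_staining"

    def validate_tiling(self, outline: RetinaOutline, tol: float = 1e-6) -> None:
        total = sum(poly.intersection(outline.usable_polygon).area
                    for poly, _s in self.regions)
        if not math.isclose(total, outline.usable_area, rel_tol=max(tol, 1e-9)):
            raise ValueError("shrinkage regions do not tile the outline")
        for _poly, s in self.regions:
            if not 0.0 < s <= 1.0:
                raise ValueError("linear_scale must be in (0, 1]")


def _ellipse(cx: float, cy: float, rx: float, ry: float) -> Polygon:
    t = np.linspace(0.0, 2.0 * np.pi, _ELLIPSE_SEGMENTS, endpoint=False)
    return Polygon(np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)]))


def make_outline(antero_posterior_diameter: float,
                 dorso_ventral_diameter: float,
                 optic_disk: tuple[tuple[float, float], float] | None = None,
                 falciform: Polygon | list[tuple[float, float]] | None = None,
                 eye_side: str = "left") -> RetinaOutline:
    """Build a flattened hemi-elliptical retina outline.

    The boundary is an ellipse with half-axes (AP/2, DV/2) centred at the
    origin (+x temporal, +y dorsal in left-eye convention).  ``optic_disk`` is
    ((cx, cy), radius); ``falciform`` an arbitrary gap polygon.  For a right
    eye all geometry is mirrored about the y-axis.
    """
    if antero_posterior_diameter <= 0 or dorso_ventral_diameter <= 0:
        raise ValueError("diameters must be positive")
    rx = antero_posterior_diameter / 2.0
    ry = dorso_ventral_diameter / 2.0
    boundary = _ellipse(0.0, 0.0, rx, ry)
    holes: list[Polygon] = []
    if optic_disk is not None:
        (cx, cy), r = optic_disk
        holes.append(_ellipse(cx, cy, r, r))
    if falciform is not None:
        poly = falciform if isinstance(falciform, Polygon) else Polygon(falciform)
        holes.append(poly)
    if eye_side == "right":
        boundary = shp_scale(boundary, xfact=-1.0, yfact=1.0, origin=(0, 0))
        holes = [shp_scale(h, xfact=-1.0, yfact=1.0, origin=(0, 0)) for h in holes]
    return RetinaOutline(boundary=boundary, holes=tuple(holes),
                         eye_side=eye_side,
                         axes=(antero_posterior_diameter, dorso_ventral_diameter))


def sample_point_process(field: DensityField, outline: RetinaOutline,
                         seed: int, cell_type: str = "single_cone") -> CellMap:
    """Draw cells from an inhomogeneous Poisson process with intensity ``field``.

    Thinning construction: a homogeneous process at the field's supremum over
    the bounding box is generated, restricted to the usable tissue, and each
    candidate kept with probability field/sup.  Expected count equals the
    integral of the field over the usable area; reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    poly = outline.usable_polygon
    x0, y0, x1, y1 = poly.bounds
    sup = field.upper_bound((x0, y0, x1, y1))
    if not np.isfinite(sup):
        raise ValueError("density field is unbounded on the outline")
    if sup <= 0:
        empty = np.empty(0)
        return CellMap(empty, empty.copy(),
                       np.empty(0, dtype=object), outline, seed)
    area_box = (x1 - x0) * (y1 - y0)
    n = rng.poisson(sup * area_box)
    x = rng.uniform(x0, x1, n)
    y = rng.uniform(y0, y1, n)
    keep = outline.contains_points(x, y)
    x, y = x[keep], y[keep]
    p = np.asarray(eval_density(field, x, y)) / sup
    keep = rng.uniform(size=len(x)) < p
    x, y = x[keep], y[keep]
    types = np.full(len(x), cell_type, dtype=object)
    return CellMap(x, y, types, outline, seed)


def _unit_cell_offsets(pattern: str) -> list[tuple[float, float, str]]:
    """Fractional (u, v, type) offsets of one mosaic unit cell."""
    if pattern == "square_2to1":
        return [(0.0, 0.0, "single_cone"),
                (0.5, 0.0, "twin_cone"),
                (0.0, 0.5, "twin_cone")]
    # clover variants: central single, four unshared twins
    return [(0.5, 0.5, "single_cone"),
            (0.25, 0.25, "twin_cone"), (0.75, 0.25, "twin_cone"),
            (0.25, 0.75, "twin_cone"), (0.75, 0.75, "twin_cone")]


def mosaic_lattice(spec: MosaicSpec, bounds: tuple[float, float, float, float],
                   seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-clipping lattice positions covering ``bounds`` (x, y, cell_type).

    Interior unit cells carry the exact pattern ratio (2:1 or 4:1) for any
    pitch; jitter displaces positions but never changes per-cell membership.
    """
    x0, y0, x1, y1 = bounds
    rng = np.random.default_rng(seed)
    p = spec.pitch
    if spec.pattern == "triple_random":
        area = (x1 - x0) * (y1 - y0)
        n = rng.poisson(area / p ** 2)
        x = rng.uniform(x0, x1, n)
        y = rng.uniform(y0, y1, n)
        return x, y, np.full(n, "triple_cone", dtype=object)
    offsets = _unit_cell_offsets(spec.pattern)
    shear = spec.shear if spec.pattern == "clover_skewed" else 0.0
    # emit only COMPLETE unit cells covering the (sheared) bounding box, so
    # the twin:single ratio is exact before clipping for any bounds and pitch
    pad = abs(shear) * max(abs(y0), abs(y1)) + p
    i = np.arange(math.floor((x0 - pad) / p), math.ceil((x1 + pad) / p) + 1)
    j = np.arange(math.floor(y0 / p) - 1, math.ceil(y1 / p) + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    xs, ys, ts = [], [], []
    for u, v, ctype in offsets:
        cy = (jj + v) * p
        cx = (ii + u) * p + shear * cy
        xs.append(cx.ravel())
        ys.append(cy.ravel())
        ts.append(np.full(cx.size, ctype, dtype=object))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t = np.concatenate(ts)
    if spec.jitter_sd > 0:
        x = x + rng.normal(0.0, spec.jitter_sd, len(x))
        y = y + rng.normal(0.0, spec.jitter_sd, len(y))
    return x, y, t


def lay_mosaic(spec: MosaicSpec, region: Polygon, seed: int,
               outline: RetinaOutline | None = None) -> CellMap:
    """Lay a regular cone mosaic inside ``region``, clipped to its polygon.

    If ``outline`` is omitted, the region itself becomes the CellMap outline.
    """
    x, y, t = mosaic_lattice(spec, region.bounds, seed)
    keep = shapely.contains_xy(region, x, y)
    x, y, t = x[keep], y[keep], t[keep]
    if outline is None:
        ap = region.bounds[2] - region.bounds[0]
        dv = region.bounds[3] - region.bounds[1]
        outline = RetinaOutline(boundary=region, holes=(), eye_side="left",
                                axes=(max(ap, 1e-9), max(dv, 1e-9)))
    return CellMap(x, y, t, outline, seed)


def quadrant_regions(outline: RetinaOutline) -> list[Polygon]:
    """Split the usable area into four quadrant regions about the bbox center."""
    x0, y0, x1, y1 = outline.boundary.bounds
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    usable = outline.usable_polygon
    out = []
    for qx0, qx1 in ((x0 - 1, cx), (cx, x1 + 1)):
        for qy0, qy1 in ((y0 - 1, cy), (cy, y1 + 1)):
            q = Polygon([(qx0, qy0), (qx1, qy0), (qx1, qy1), (qx0, qy1)])
            out.append(usable.intersection(q))
    return out


def apply_shrinkage(cellmap: CellMap, spec: ShrinkageSpec):
    """Distort a CellMap by region-wise isotropic shrinkage.

    Each cell is rescaled about the centroid of its containing region by that
    region's linear_scale; the returned table reports per-region areas before
    and after (area ratio = linear_scale^2).  Cell counts are conserved
    exactly; a cell falling in no region is a geometry error.
    """
    import pandas as pd

    x = cellmap.x.copy()
    y = cellmap.y.copy()
    assigned = np.zeros(len(x), dtype=bool)
    rows = []
    for idx, (poly, s) in enumerate(spec.regions):
        m = shapely.contains_xy(poly, x, y) | shapely.intersects_xy(poly.boundary, x, y)
        m &= ~assigned
        cx, cy = poly.centroid.x, poly.centroid.y
        x[m] = cx + s * (x[m] - cx)
        y[m] = cy + s * (y[m] - cy)
        assigned |= m
        after = shp_scale(poly, xfact=s, yfact=s, origin=(cx, cy))
        rows.append({"region_id": idx, "linear_scale": s,
                     "area_before_mm2": poly.area, "area_after_mm2": after.area,
                     "n_cells": int(m.sum())})
    if not assigned.all():
        raise ValueError(f"{int((~assigned).sum())} cells fall in no shrinkage region")
    table = pd.DataFrame(rows)
    distorted = CellMap(x, y, cellmap.cell_type.copy(), cellmap.outline, cellmap.seed)
    return distorted, table
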