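"""Default synthetic-retina parameters for a small foveate triplefin.

These defaults emulate the flattened left-eye wholemount of a ~4 cm rocky
shore triplefin: a hemi-elliptical outline whose usable area is 16.09 mm^2
(dorso-ventral / antero-posterior axis ratio 0.863), an optic-disk hole with
a falciform gap running naso-ventrally, a fovea at 50 deg temporal / 30 deg
dorsal, single cones peaking at 30,800 /mm^2 (mean ~10,200), twin cones at
104,400 (mean ~23,300), RGCs at 81,000 (mean ~32,400), and a restricted
triple-cone patch (~0.32 mm^2, mean ~16,700, peak 30,400) between optic disk
and fovea.  Rods (not counted by the sampling design) are modelled as a field
suppressed to zero in the foveal and triple-cone areas.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import Polygon, Point

from .synthetic import DensityField, RetinaOutline, make_outline

__all__ = [
    "AXIS_RATIO", "USABLE_AREA_MM2", "FOVEA_DEG",
    "FOVEAL_AREA_MM2", "TRIPLE_AREA_MM2",
    "default_outline", "fovea_center", "foveal_region", "triple_patch",
    "default_fields",
]

AXIS_RATIO = 0.863          # dorso-ventral / antero-posterior diameter
USABLE_AREA_MM2 = 16.09     # flattened wholemount area minus holes
FOVEA_DEG = (50.0, 30.0)    # (temporal, dorsal), retina diameter = 180 deg
FOVEAL_AREA_MM2 = 0.95      # high-resolution sampling stratum
TRIPLE_AREA_MM2 = 0.32      # restricted triple-cone patch

_OPTIC_DISK = ((-0.25, -0.15), 0.15)


def _falciform_polygon() -> Polygon:
    """Thin gap running naso-ventrally from near the optic disk."""
    p0 = np.array([-0.42, -0.32])
    p1 = np.array([-1.55, -1.05])
    d = p1 - p0
    n = np.array([-d[1], d[0]])
    n = 0.06 * n / np.linalg.norm(n)  # half-width 60 um
    return Polygon([tuple(p0 + n), tuple(p1 + n), tuple(p1 - n), tuple(p0 - n)])


def default_outline(eye_side: str = "left") -> RetinaOutline:
    """Hemi-elliptical outline solved so the usable area is USABLE_AREA_MM2."""
    falciform = _falciform_polygon()
    disk_area = math.pi * _OPTIC_DISK[1] ** 2
    target_ellipse = USABLE_AREA_MM2 + disk_area + falciform.area
    # pi * a * b with b = AXIS_RATIO * a
    a = math.sqrt(target_ellipse / (math.pi * AXIS_RATIO))
    return make_outline(2 * a, 2 * AXIS_RATIO * a, optic_disk=_OPTIC_DISK,
                        falciform=falciform, eye_side=eye_side)


def fovea_center(outline: RetinaOutline) -> tuple[float, float]:
    """Ground-truth fovea position from its angular coordinates."""
    x0, y0, x1, y1 = outline.boundary.bounds
    half_w, half_h = (x1 - x0) / 2.0, (y1 - y0) / 2.0
    sign = 1.0 if outline.eye_side == "left" else -1.0
    t_deg, d_deg = FOVEA_DEG
    return (sign * t_deg / 90.0 * half_w, d_deg / 90.0 * half_h)


def foveal_region(outline: RetinaOutline) -> Polygon:
    """Circular foveal sampling stratum of area FOVEAL_AREA_MM2."""
    r = math.sqrt(FOVEAL_AREA_MM2 / math.pi)
    return Point(fovea_center(outline)).buffer(r, quad_segs=64)


def triple_patch(outline: RetinaOutline) -> Polygon:
    """Triple-cone patch between the optic disk and the fovea."""
    fx, fy = fovea_center(outline)
    dx, dy = _OPTIC_DISK[0]
    cx, cy = (fx + dx) / 2.0, (fy + dy) / 2.0
    r = math.sqrt(TRIPLE_AREA_MM2 / math.pi)
    return Point(cx, cy).buffer(r, quad_segs=64)


def default_fields(outline: RetinaOutline,
                   density_scale: float = 1.0) -> dict[str, DensityField]:
    """Per-type density fields matching the default study conditions.

    ``density_scale`` scales every field uniformly — useful for fast,
    reduced-size simulations that keep the spatial structure intact.
    """
    fc = fovea_center(outline)
    patch = triple_patch(outline)
    px, py = patch.centroid.x, patch.centroid.y
    s = density_scale
    sign = 1.0 if outline.eye_side == "left" else -1.0

    def grad(gx, gy):
        return (sign * gx * s, gy * s)

    fields = {
        "single_cone": DensityField(base=10_000 * s, gradient_vector=grad(800, 500),
                                    peaks=(((fc), 30_800 * s, 0.25),)),
        "twin_cone": DensityField(base=22_500 * s, gradient_vector=grad(2_000, 1_200),
                                  peaks=(((fc), 104_400 * s, 0.25),)),
        # patch plateau 16,700 plus a bump whose center value reaches 30,400
        "triple_cone": DensityField(base=0.0,
                                    peaks=((((px, py)), (30_400 - 16_700) * s, 0.15),),
                                    patches=((patch, 16_700 * s),)),
        "rgc": DensityField(base=31_500 * s, gradient_vector=grad(2_000, 1_200),
                            peaks=(((fc), 81_000 * s, 0.35),)),
        "rod": DensityField(base=80_000 * s, gradient_vector=grad(-2_000, -1_000),
                            suppression_masks=((fc, 0.45), ((px, py), 0.35))),
    }
    return fields
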