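"""Region-wise shrinkage factors and density correction for stained tissue.

Nissl staining shrinks wholemount tissue non-uniformly.  The wholemount is
divided into regions whose outlines are digitised before and after staining;
each region's shrinkage factor is the areal ratio after/before.  Densities
measured on the stained (shrunken) tissue are multiplied by their region's
factor, converting them back to pre-staining tissue scale: a density measured
on tissue shrunk to a fraction f of its original area overestimates the true
density by 1/f, so multiplying by f (< 1) undoes the inflation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .fractionator import CountingSite

__all__ = ["RegionShrinkage", "shrinkage_factors", "correct_densities"]


@dataclass(frozen=True)
class RegionShrinkage:
    """One region's pre/post-staining outlines and areal shrinkage factor."""

    region_id: int
    polygon_before: Polygon
    polygon_after: Polygon
    area_before: float
    area_after: float
    factor: float

    def __post_init__(self) -> None:
        if self.area_before <= 0 or self.area_after <= 0:
            raise ValueError("region areas must be positive")
        if not 0.0 < self.factor <= 1.2:
            raise ValueError("shrinkage factor outside the plausible (0, 1.2] range")


def shrinkage_factors(regions_before: list[Polygon],
                      regions_after: list[Polygon]) -> list[RegionShrinkage]:
    """Areal shrinkage factor (after/before) for each corresponding region pair."""
    if len(regions_before) != len(regions_after):
        raise ValueError("regions_before and regions_after must correspond one-to-one")
    out = []
    for i, (b, a) in enumerate(zip(regions_before, regions_after)):
        out.append(RegionShrinkage(region_id=i, polygon_before=b, polygon_after=a,
                                   area_before=b.area, area_after=a.area,
                                   factor=a.area / b.area))
    return out


def correct_densities(sites: list[CountingSite],
                      shrinkage: list[RegionShrinkage]) -> pd.DataFrame:
    """Rescale per-site densities measured on stained tissue to pre-staining scale.

    Each site (post-staining coordinates) is assigned to the after-region
    containing its frame centre; every per-type density is multiplied by that
    region's factor.  Counts are untouched.  Returns a tidy table with one row
    per (site, cell type).
    """
    rows = []
    for s in sites:
        if s.status == "omitted":
            continue
        cx, cy = s.center
        region = None
        for r in shrinkage:
            if shapely.contains_xy(r.polygon_after, cx, cy) or \
               shapely.intersects_xy(r.polygon_after.boundary, cx, cy):
                region = r
                break
        if region is None:
            # edge frames keep clipped area inside a region while their
            # centre sits just outside; assign to the nearest region within
            # one frame side, else it is a genuine assignment error
            pt = shapely.points(cx, cy)
            near = min(shrinkage, key=lambda r: r.polygon_after.distance(pt))
            if near.polygon_after.distance(pt) <= s.frame_side:
                region = near
            else:
                raise ValueError(
                    f"site {s.site_id} center lies outside all after-regions")
        for ctype, q in s.counts.items():
            raw = q / s.clipped_area
            rows.append({"site_id": s.site_id, "x_mm": cx, "y_mm": cy,
                         "cell_type": ctype, "count": q,
                         "raw_density_mm2": raw,
                         "region_id": region.region_id,
                         "shrinkage_factor": region.factor,
                         "corrected_density_mm2": raw * region.factor})
    return pd.DataFrame(rows, columns=["site_id", "x_mm", "y_mm", "cell_type",
                                       "count", "raw_density_mm2", "region_id",
                                       "shrinkage_factor", "corrected_density_mm2"])
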