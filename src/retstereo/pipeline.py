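"""End-to-end runner: simulate -> sample -> estimate -> correct -> map -> acuity.

Mirrors a complete wholemount analysis session: a synthetic retina with known
density fields is generated, sampled with stratified optical-fractionator
designs (a coarse grid over the general retina, finer grids over the foveal
and triple-cone strata), per-stratum densities/totals/CEs are estimated, the
ganglion-cell stage is distorted by region-wise shrinkage and corrected back,
topographic maps are interpolated, the fovea is localized in angular
coordinates, and the anatomical spatial resolving power is computed from the
measured foveal peak densities.

One master seed determines every stage: child seeds are drawn from
``numpy.random.SeedSequence(master).spawn`` in a fixed stage order, so a rerun
with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.affinity import scale as shp_scale
from shapely.geometry import Polygon

from . import defaults, io, optics, topography
from .fractionator import (CountingSite, count_sites, design_grid, estimate_stratum,
                           place_frames)
from .shrinkage import correct_densities, shrinkage_factors
from .synthetic import (CellMap, ShrinkageSpec, apply_shrinkage, quadrant_regions,
                        sample_point_process)

log = logging.getLogger("retstereo")

__all__ = ["RunConfig", "StratumConfig", "run_pipeline", "split_seeds"]


@dataclass(frozen=True)
class StratumConfig:
    target_sites: int
    frame_side: float


@dataclass
class RunConfig:
    """Structured configuration for one pipeline run."""

    seed: int = 0
    eye_side: str = "left"
    density_scale: float = 1.0
    cell_types: tuple[str, ...] = ("single_cone", "twin_cone", "triple_cone", "rgc")
    general: StratumConfig = field(default_factory=lambda: StratumConfig(200, 0.050))
    foveal: StratumConfig | None = field(default_factory=lambda: StratumConfig(60, 0.025))
    triple: StratumConfig | None = field(default_factory=lambda: StratumConfig(14, 0.050))
    shrinkage_scales: tuple[float, ...] = (0.97, 0.98, 0.96, 0.99)
    raster_resolution: float = 0.025
    lens_radius: float = 0.70
    matthiessen_ratio: float = optics.MATTHIESSEN_RATIO_TELEOST
    write_cells: bool = False
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("general", "foveal", "triple"):
            if d[k] is not None:
                d[k] = dict(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for k in ("general", "foveal", "triple"):
            if d.get(k) is not None and not isinstance(d[k], StratumConfig):
                d[k] = StratumConfig(**d[k])
        if "cell_types" in d:
            d["cell_types"] = tuple(d["cell_types"])
        if "shrinkage_scales" in d:
            d["shrinkage_scales"] = tuple(d["shrinkage_scales"])
        return cls(**d)


def split_seeds(master: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2^31) from one master seed."""
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _simulate(config: RunConfig, seeds: list[int]):
    outline = defaults.default_outline(config.eye_side)
    fields = defaults.default_fields(outline, config.density_scale)
    maps = [sample_point_process(fields[t], outline, seeds[i], cell_type=t)
            for i, t in enumerate(config.cell_types)]
    cellmap = CellMap.concat(maps)
    log.info("simulate: %d cells over %.2f mm^2 (%s)", len(cellmap),
             outline.usable_area, ", ".join(config.cell_types))
    return outline, fields, cellmap


def _strata_polygons(config: RunConfig, outline) -> dict[str, Polygon]:
    usable = outline.usable_polygon
    strata: dict[str, Polygon] = {}
    if config.foveal is not None:
        strata["foveal_area"] = usable.intersection(defaults.foveal_region(outline))
    if config.triple is not None:
        patch = defaults.triple_patch(outline)
        if "foveal_area" in strata:
            patch = patch.difference(strata["foveal_area"])
        strata["triple_cone_area"] = usable.intersection(patch)
    general = usable
    for poly in strata.values():
        general = general.difference(poly)
    strata["general_retina"] = general
    return strata


def _sample_stratum(cellmap, poly, scfg: StratumConfig, stratum: str, seed: int):
    design = design_grid(poly, scfg.target_sites, scfg.frame_side, seed,
                         stratum=stratum)
    sites = place_frames(design, poly)
    sites = count_sites(cellmap, sites)
    log.info("sample[%s]: step %.4f mm, %d sites, asf %.4f", stratum,
             design.grid_step, len(sites),
             sum(s.clipped_area for s in sites) / poly.area)
    return design, sites


def _shrinkage_stage(config: RunConfig, outline, rgc_map: CellMap, seed: int):
    """Distort the RGC tissue region-wise, re-sample it, correct densities."""
    regions_before = [r for r in quadrant_regions(outline) if r.area > 0]
    scales = list(config.shrinkage_scales)[: len(regions_before)]
    while len(scales) < len(regions_before):
        scales.append(scales[-1])
    spec = ShrinkageSpec(regions=tuple(zip(regions_before, scales)))
    distorted, area_table = apply_shrinkage(rgc_map, spec)
    regions_after = [shp_scale(p, xfact=s, yfact=s, origin=(p.centroid.x, p.centroid.y))
                     for p, s in spec.regions]
    shr = shrinkage_factors(regions_before, regions_after)
    seeds = split_seeds(seed, len(regions_after))
    sites: list[CountingSite] = []
    n_regions = len(regions_after)
    per_region = max(config.general.target_sites // n_regions, 2)
    for i, poly in enumerate(regions_after):
        design = design_grid(poly, per_region, config.general.frame_side, seeds[i],
                             stratum="general_retina")
        placed = place_frames(design, poly)
        placed = count_sites(distorted, placed)
        offset = len(sites)
        sites.extend(dataclasses.replace(s, site_id=s.site_id + offset)
                     for s in placed)
    corrected = correct_densities(sites, shr)
    log.info("shrinkage: %d regions, factors %s, %d RGC sites",
             n_regions, [round(r.factor, 4) for r in shr], len(sites))
    return shr, area_table, corrected


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a result bundle and (optionally) writes files."""
    stage_seeds = split_seeds(config.seed, 8)
    sim_seeds = split_seeds(stage_seeds[0], len(config.cell_types))
    outline, fields, cellmap = _simulate(config, sim_seeds)
    strata = _strata_polygons(config, outline)

    stratum_cfgs = {"general_retina": config.general}
    if config.foveal is not None:
        stratum_cfgs["foveal_area"] = config.foveal
    else:
        log.warning("no foveal stratum configured; general-only estimates")
    if config.triple is not None:
        stratum_cfgs["triple_cone_area"] = config.triple

    samp_seeds = split_seeds(stage_seeds[1], len(stratum_cfgs))
    designs, all_sites, estimates = {}, {}, {}
    for i, (name, scfg) in enumerate(stratum_cfgs.items()):
        poly = strata[name]
        design, sites = _sample_stratum(cellmap, poly, scfg, name, samp_seeds[i])
        designs[name] = design
        all_sites[name] = sites
        estimates[name] = estimate_stratum(sites, poly.area,
                                           cell_types=config.cell_types)
        log.info("estimate[%s]: n=%d asf=%.4f CE=%s", name,
                 estimates[name].n_sites, estimates[name].asf,
                 {t: round(c, 3) for t, c in estimates[name].ce.items()})

    combined_totals = {
        t: sum(est.total_estimate.get(t, 0.0) for est in estimates.values())
        for t in config.cell_types}

    shr = area_table = corrected_rgc = None
    if "rgc" in config.cell_types:
        shr, area_table, corrected_rgc = _shrinkage_stage(
            config, outline, cellmap.of_type("rgc"), stage_seeds[2])

    # topographic maps from the pooled site densities
    cone_types = [t for t in config.cell_types if t.endswith("_cone")]
    maps = {}
    # heavily clipped edge frames give wildly noisy per-site densities
    # (few cells over a sliver area); keep them in the estimator but not
    # in the interpolated maps
    site_pool = [s for sites in all_sites.values() for s in sites
                 if s.clipped_area >= 0.5 * s.frame_side ** 2]
    xy = np.array([s.center for s in site_pool])
    for t in cone_types + (["rgc"] if "rgc" in config.cell_types else []):
        dens = np.array([s.counts.get(t, 0) / s.clipped_area for s in site_pool])
        maps[t] = topography.interpolate_map(xy, dens, outline,
                                             config.raster_resolution, cell_type=t)
    summed = topography.sum_cone_maps([maps[t] for t in cone_types]) \
        if cone_types else None
    fovea = None
    if summed is not None:
        px, py, pval = summed.peak
        fovea = topography.fovea_position_deg((px, py), outline)
        log.info("fovea: peak %.0f /mm^2 at (%.3f, %.3f) -> %.1f deg temporal, "
                 "%.1f deg dorsal", pval, px, py,
                 fovea.degrees_temporal, fovea.degrees_dorsal)

    model = optics.OpticalModel(config.lens_radius, config.matthiessen_ratio)
    twin_peak = maps["twin_cone"].peak[2] if "twin_cone" in maps else 0.0
    single_peak = maps["single_cone"].peak[2] if "single_cone" in maps else 0.0
    acuity = {mode: optics.acuity_estimate(model, twin_peak, single_peak, mode)
              for mode in ("conservative", "maximal")}
    for mode, est in acuity.items():
        log.info("srp[%s]: D=%.0f /mm^2 f_N=%.2f cpd MSA=%.3f deg",
                 mode, est.density, est.nyquist, est.msa)

    results = {
        "config": config, "outline": outline, "fields": fields,
        "cellmap": cellmap, "strata": strata, "designs": designs,
        "sites": all_sites, "estimates": estimates,
        "combined_totals": combined_totals,
        "shrinkage": shr, "shrinkage_areas": area_table,
        "corrected_rgc": corrected_rgc,
        "maps": maps, "summed_cone_map": summed, "fovea": fovea,
        "optical_model": model, "acuity": acuity,
    }
    if config.output_dir is not None:
        _write_outputs(results)
    return results


def _report_dict(results: dict) -> dict:
    config: RunConfig = results["config"]
    est_block = {}
    for name, est in results["estimates"].items():
        est_block[name] = {
            "n_sites": est.n_sites, "region_area_mm2": est.region_area,
            "sampled_area_mm2": est.sampled_area, "asf": est.asf,
            "sum_counts": est.sum_counts, "mean_density_mm2": est.mean_density,
            "total_estimate": est.total_estimate, "scheaffer_ce": est.ce}
    report = {
        "seed": config.seed,
        "usable_area_mm2": results["outline"].usable_area,
        "strata": est_block,
        "combined_totals": results["combined_totals"],
    }
    if results["shrinkage"] is not None:
        report["shrinkage_factors"] = {r.region_id: r.factor
                                       for r in results["shrinkage"]}
    if results["fovea"] is not None:
        px, py, pval = results["summed_cone_map"].peak
        report["fovea"] = {
            "peak_xy_mm": [px, py], "peak_density_mm2": pval,
            "degrees_temporal": results["fovea"].degrees_temporal,
            "degrees_dorsal": results["fovea"].degrees_dorsal,
            "center_definition": "bounding-box center of boundary polygon",
        }
    model = results["optical_model"]
    report["acuity"] = {
        "pnd_mm": optics.round_half_up(model.pnd, 2),
        **{mode: {"density_mm2": est.density,
                  "nyquist_cpd": optics.round_half_up(est.nyquist, 1),
                  "msa_deg": optics.round_half_up(est.msa, 2)}
           for mode, est in results["acuity"].items()},
    }
    return report


def _write_outputs(results: dict) -> None:
    config: RunConfig = results["config"]
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    cfg_hash = io.config_hash(cfg_dict)
    prov = {"cfg_hash": cfg_hash, "seed": config.seed}
    io.write_outline(outdir / "outline.geojson", results["outline"], **prov)
    for name, sites in results["sites"].items():
        io.write_site_table(outdir / f"sites_{name}.csv", sites, **prov)
    if config.write_cells:
        io.write_cellmap(outdir / "cells.csv", results["cellmap"], **prov)
    if results["corrected_rgc"] is not None:
        with open(outdir / "rgc_corrected.csv", "w", encoding="utf-8") as fh:
            for line in io.provenance_lines(**prov):
                fh.write(line + "\n")
            results["corrected_rgc"].to_csv(fh, index=False)
    for t, dmap in results["maps"].items():
        io.write_map_text(outdir / f"map_{t}.txt", dmap, **prov)
    if results["summed_cone_map"] is not None:
        io.write_map_text(outdir / "map_all_cones.txt",
                          results["summed_cone_map"], **prov)
    io.write_report(outdir / "report.json", _report_dict(results), **prov)
    log.info("wrote outputs to %s (config %s)", outdir, cfg_hash)
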