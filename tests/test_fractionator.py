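"""Fractionator sampling: grid design, counting-frame rule, estimators, CE,
and imputation of compromised sites."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import box

from retstereo.fractionator import (CountingSite, SamplingDesign, count_frame,
                                    count_sites, design_grid, estimate_stratum,
                                    impute_single_counts, place_frames,
                                    scheaffer_ce)
from retstereo.synthetic import CellMap, DensityField, make_outline, \
    sample_point_process


def _site(cx, cy, side, counts=None, status="ok", site_id=0,
          stratum="general_retina", clipped_area=None):
    return CountingSite(site_id=site_id, center=(cx, cy), frame_side=side,
                        clipped_frame=None,
                        clipped_area=side**2 if clipped_area is None else clipped_area,
                        stratum=stratum, counts=counts or {}, status=status)


class TestDesignGrid:
    def test_paper_scale_step_in_range(self):
        # 16.09 mm^2 and 200 sites give a grid pitch of ~283.6 um,
        # inside the 250-300 um range typical of wholemount designs
        region = box(0, 0, 4.02, 4.0024)  # area ~16.09
        d = design_grid(region, 200, 0.05, seed=1)
        assert d.grid_step == pytest.approx(math.sqrt(region.area / 200))
        assert 0.250 <= d.grid_step <= 0.300
        assert d.grid_step == pytest.approx(0.2836, abs=5e-4)

    def test_foveal_scale_step(self):
        region = box(0, 0, 1, 1)
        d = design_grid(region, 100, 0.025, seed=0)
        assert d.grid_step == pytest.approx(0.1)

    def test_same_seed_same_offset(self):
        region = box(0, 0, 2, 2)
        a = design_grid(region, 50, 0.05, seed=42)
        b = design_grid(region, 50, 0.05, seed=42)
        assert a.origin_offset == b.origin_offset

    def test_overlapping_frames_rejected(self):
        with pytest.raises(ValueError):
            design_grid(box(0, 0, 1, 1), 100, frame_side=0.2, seed=0)

    def test_realized_site_count_near_target(self, outline):
        region = outline.usable_polygon
        for seed in range(5):
            d = design_grid(region, 200, 0.05, seed=seed)
            n = len(place_frames(d, region))
            assert abs(n - 200) <= 0.15 * 200


class TestPlaceFrames:
    def test_interior_grid_counts(self):
        design = SamplingDesign("general_retina", frame_side=0.2, grid_step=1.0,
                                origin_offset=(0.5, 0.5), seed=0)
        sites = place_frames(design, box(0, 0, 3, 3))
        assert len(sites) == 9
        assert all(s.clipped_area == pytest.approx(0.04) for s in sites)

    def test_boundary_frame_partially_clipped(self):
        design = SamplingDesign("general_retina", frame_side=0.2, grid_step=1.0,
                                origin_offset=(0.0, 0.0), seed=0)
        sites = place_frames(design, box(0, 0, 1, 1))
        corner = [s for s in sites if s.center == (0.0, 0.0)]
        assert corner and 0 < corner[0].clipped_area < 0.04

    def test_empty_region(self):
        design = SamplingDesign("general_retina", frame_side=0.2, grid_step=1.0,
                                origin_offset=(0.0, 0.0), seed=0)
        from shapely.geometry import Polygon
        assert place_frames(design, Polygon()) == []


class TestCountingFrameRule:
    def _cellmap(self, xs, ys):
        o = make_outline(10.0, 10.0)
        n = len(xs)
        return CellMap(np.asarray(xs, float), np.asarray(ys, float),
                       np.full(n, "rgc", dtype=object), o)

    def test_forbidden_and_inclusion_edges(self):
        site = _site(0.5, 0.5, 1.0)  # frame [0,1]x[0,1]
        cm = self._cellmap([0.0, 1.0, 0.5, 0.5, 0.0, 1.0],
                           [0.5, 0.5, 0.0, 1.0, 0.0, 1.0])
        counted = count_frame(cm, site).counts.get("rgc", 0)
        # left edge, bottom edge, bottom-left / top-left / bottom-right
        # corners forbidden; right edge, top edge, top-right corner included
        assert counted == 3

    def test_lattice_count_exactly_k_squared(self):
        # a frame of side k*p over a pitch-p lattice counts exactly k^2 cells
        # for ANY origin: the half-open rule admits exactly k lattice columns
        # and k rows.  Brute-force over random origins.
        p, k = 0.1, 3
        g = np.arange(-20, 21) * p
        gx, gy = np.meshgrid(g, g)
        cm = self._cellmap(gx.ravel(), gy.ravel())
        rng = np.random.default_rng(0)
        for _ in range(20):
            cx, cy = rng.uniform(-0.5, 0.5, 2)
            site = _site(cx, cy, k * p)
            assert count_frame(cm, site).counts["rgc"] == k**2

    def test_tiling_counts_every_cell_once(self):
        # frames tiling a region at step = frame_side count each cell exactly
        # once, including cells dropped exactly on shared edges and corners
        side = 1.0
        rng = np.random.default_rng(1)
        xs = np.concatenate([rng.uniform(0, 3, 200),
                             np.repeat([1.0, 2.0], 3), rng.uniform(0, 3, 6)])
        ys = np.concatenate([rng.uniform(0, 3, 200),
                             rng.uniform(0, 3, 6), np.repeat([1.0, 2.0], 3)])
        cm = self._cellmap(xs, ys)
        total = 0
        for i in range(3):
            for j in range(3):
                site = _site(i + 0.5, j + 0.5, side)
                total += count_frame(cm, site).counts.get("rgc", 0)
        # cells on the outer forbidden edges (x=0 or y=0) belong to no frame;
        # none were generated on them, all others counted exactly once
        assert total == len(xs)

    @given(x=st.floats(0.001, 1.999), y=st.floats(0.001, 1.999))
    def test_rule_exclusive_and_exhaustive(self, x, y):
        cm = self._cellmap([x], [y])
        hits = sum(count_frame(cm, _site(i + 0.5, j + 0.5, 1.0)).counts.get("rgc", 0)
                   for i in range(2) for j in range(2))
        assert hits == 1


class TestEstimateStratum:
    def test_homogeneous_arithmetic(self):
        sites = [_site(i * 0.3, 0.0, 0.05, {"rgc": q}, site_id=i)
                 for i, q in enumerate([2, 3] * 100)]  # sum 500 over 200 frames
        est = estimate_stratum(sites, region_area=15.0)
        assert est.asf == pytest.approx(200 * 0.0025 / 15.0)
        assert est.mean_density["rgc"] == pytest.approx(1_000.0)
        assert est.total_estimate["rgc"] == pytest.approx(15_000.0)
        assert est.asf * est.region_area == pytest.approx(est.sampled_area)

    def test_published_style_asf(self):
        # 167 full 50 um frames on a 15.14 mm^2 stratum
        sites = [_site(i * 0.3, 0.0, 0.05, {"single_cone": 25}, site_id=i)
                 for i in range(167)]
        est = estimate_stratum(sites, region_area=15.14)
        assert round(est.asf, 4) == 0.0276

    def test_zero_counts(self):
        sites = [_site(i * 1.0, 0.0, 0.05, {}, site_id=i) for i in range(10)]
        est = estimate_stratum(sites, 1.0, cell_types=("rgc",))
        assert est.mean_density["rgc"] == 0.0
        assert est.total_estimate["rgc"] == 0.0
        assert est.asf == pytest.approx(10 * 0.0025)

    def test_omitted_sites_excluded_from_both_sides(self):
        ok = [_site(i * 1.0, 0.0, 0.1, {"rgc": 5}, site_id=i) for i in range(4)]
        omitted = [_site(9.0, 0.0, 0.1, status="omitted", site_id=99)]
        est = estimate_stratum(ok + omitted, region_area=2.0)
        assert est.n_sites == 4
        assert est.sampled_area == pytest.approx(4 * 0.01)
        assert est.sum_counts["rgc"] == 20

    def test_errors(self):
        sites = [_site(0, 0, 0.1, {"rgc": 1}), _site(1, 0, 0.1, {"rgc": 2})]
        with pytest.raises(ValueError):
            estimate_stratum(sites, region_area=0.0)
        with pytest.raises(ValueError):
            estimate_stratum([s for s in sites][:1], region_area=1.0)


class TestScheafferCE:
    def test_constant_counts_zero(self):
        assert scheaffer_ce([7, 7, 7, 7], 0.03) == 0.0

    def test_census_zero(self):
        assert scheaffer_ce([2, 9, 4], 1.0) == 0.0

    def test_textbook_value(self):
        # survey-sampling oracle: N = n/asf = 300 units, qbar = 3, s^2 = 1;
        # CE = sqrt((1 - n/N) * s^2 / n) / qbar = sqrt(0.99 / 3) / 3
        n, asf = 3, 0.01
        q = [2, 3, 4]
        n_units = n / asf
        expected = math.sqrt((1 - n / n_units) * np.var(q, ddof=1) / n) / np.mean(q)
        got = scheaffer_ce(q, asf)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.1914, abs=1e-4)

    def test_errors(self):
        with pytest.raises(ValueError):
            scheaffer_ce([5], 0.05)
        with pytest.raises(ValueError):
            scheaffer_ce([1, 2], 0.0)

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=30),
           st.floats(0.001, 1.0))
    def test_nonnegative(self, counts, asf):
        assert scheaffer_ce(counts, asf) >= 0.0


class TestImputation:
    def _grid_sites(self, counts_grid, step=1.0, side=0.1):
        sites = []
        sid = 0
        for j, row in enumerate(counts_grid):
            for i, c in enumerate(row):
                if c is None:
                    continue
                sites.append(_site(i * step, j * step, side, dict(c), site_id=sid))
                sid += 1
        return sites

    def test_mean_neighbor_ratio(self):
        # center site: twins readable (10), singles unreadable; neighbor
        # single/twin ratios 0.4 and 0.6 -> mean 0.5 -> imputed 5
        grid = [
            [{"twin_cone": 10, "single_cone": 4}, {"twin_cone": 10}, None],
            [{"twin_cone": 10, "single_cone": 6}, None, None],
        ]
        sites = self._grid_sites(grid)
        flagged = {1: {"single_cone"}}
        out = impute_single_counts(sites, flagged, grid_step=1.0)
        imputed = [s for s in out if s.site_id == 1][0]
        assert imputed.status == "single_imputed"
        assert imputed.counts["single_cone"] == 5

    def test_rounding_half_up(self):
        grid = [
            [{"twin_cone": 5, "single_cone": 1}, {"twin_cone": 3}],
        ]
        sites = self._grid_sites(grid)
        # ratio 0.2 -> 3 * 0.2 = 0.6 -> rounds to 1
        out = impute_single_counts(sites, {1: {"single_cone"}}, grid_step=1.0)
        assert [s for s in out if s.site_id == 1][0].counts["single_cone"] == 1

    def test_no_valid_neighbor_omitted(self):
        grid = [
            [{"twin_cone": 0, "single_cone": 0}, {"twin_cone": 10}],
        ]
        sites = self._grid_sites(grid)
        out = impute_single_counts(sites, {1: {"single_cone"}}, grid_step=1.0)
        assert [s for s in out if s.site_id == 1][0].status == "omitted"

    def test_both_types_unreadable_omitted(self):
        grid = [
            [{"twin_cone": 8, "single_cone": 3}, {"twin_cone": 9, "single_cone": 2}],
        ]
        sites = self._grid_sites(grid)
        out = impute_single_counts(sites, {1: {"single_cone", "twin_cone"}},
                                   grid_step=1.0)
        flagged_site = [s for s in out if s.site_id == 1][0]
        assert flagged_site.status == "omitted"
        assert flagged_site.counts == {}

    def test_flagged_neighbors_not_used(self):
        grid = [
            [{"twin_cone": 10, "single_cone": 9}, {"twin_cone": 10},
             {"twin_cone": 10}],
        ]
        sites = self._grid_sites(grid)
        flagged = {1: {"single_cone"}, 2: {"single_cone"}}
        out = impute_single_counts(sites, flagged, grid_step=1.0)
        # only site 0 is a usable neighbour of site 1: ratio 0.9 -> 9
        assert [s for s in out if s.site_id == 1][0].counts["single_cone"] == 9


def test_fractionator_recovers_known_total(outline):
    """One-shot sanity check of the whole sampling chain (full unbiasedness
    sweep lives in the acceptance suite)."""
    f = DensityField(base=3_000.0)
    cm = sample_point_process(f, outline, seed=12)
    region = outline.usable_polygon
    d = design_grid(region, 200, 0.05, seed=5)
    sites = count_sites(cm, place_frames(d, region))
    est = estimate_stratum(sites, region.area)
    assert est.total_estimate["single_cone"] == pytest.approx(len(cm), rel=0.10)
    assert est.ce["single_cone"] < 0.1
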