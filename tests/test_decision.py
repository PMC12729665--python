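"""Decision-surface geometry: densification, slicing, intersection, centroids."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import box

from myofat.decision import (
    DecisionSurface,
    FeasibleRegion,
    centroid_estimate,
    densify_axis,
    estimate,
    fit_surfaces,
    intersect_regions,
    slice_region,
    surfaces_from_json,
    surfaces_to_json,
)

LEVELS = np.array([0.0, 12.5, 25.0, 37.5, 50.0])


def _surface(min_field, max_field, name="cr1"):
    s, i = np.meshgrid(LEVELS, LEVELS, indexing="ij")
    return DecisionSurface(name, LEVELS, min_field(s, i), max_field(s, i))


def _raster_membership(surface, value, n=500):
    """Dense rasterization oracle for {min <= value <= max} membership."""
    from scipy.interpolate import RegularGridInterpolator
    ax = np.linspace(0, 50, n)
    ss, ii = np.meshgrid(ax, ax, indexing="ij")
    pts = np.stack([ss.ravel(), ii.ravel()], axis=1)
    lo = RegularGridInterpolator((surface.dense_axis,) * 2,
                                 surface.min_dense)(pts)
    hi = RegularGridInterpolator((surface.dense_axis,) * 2,
                                 surface.max_dense)(pts)
    return ((lo <= value) & (value <= hi)).reshape(n, n), ss, ii


class TestDensification:
    def test_axis_five_to_seventeen(self):
        dense = densify_axis(LEVELS)
        assert dense.size == 17
        assert np.all(np.isin(LEVELS, dense))

    def test_original_nodes_interpolated_exactly(self):
        surf = _surface(lambda s, i: 1500 - s - 2 * i,
                        lambda s, i: 1510 - s - 2 * i)
        idx = np.searchsorted(surf.dense_axis, LEVELS)
        assert np.allclose(surf.min_dense[np.ix_(idx, idx)], surf.min_nodes)
        assert np.allclose(surf.max_dense[np.ix_(idx, idx)], surf.max_nodes)

    def test_linear_field_reproduced_on_dense_grid(self):
        # Akima interpolation of a plane is the plane
        surf = _surface(lambda s, i: 2 + 0.1 * s + 0.3 * i,
                        lambda s, i: 3 + 0.1 * s + 0.3 * i)
        ds, di = np.meshgrid(surf.dense_axis, surf.dense_axis, indexing="ij")
        assert np.allclose(surf.min_dense, 2 + 0.1 * ds + 0.3 * di,
                           atol=1e-9)


class TestFitSurfaces:
    def test_single_record_per_node_degenerates(self, noisefree_records):
        one = noisefree_records[noisefree_records["repeat"] == 1]
        surfaces = fit_surfaces(one)
        for s in surfaces.values():
            assert np.allclose(s.min_nodes, s.max_nodes)

    def test_envelope_contains_training_records(self, split_pair):
        train, _ = split_pair
        surfaces = fit_surfaces(train)
        for crit, surf in surfaces.items():
            for (sat, imat), grp in train.groupby(["sat", "imat"]):
                r = int(np.argmin(np.abs(LEVELS - sat)))
                c = int(np.argmin(np.abs(LEVELS - imat)))
                assert grp[crit].min() >= surf.min_nodes[r, c] - 1e-12
                assert grp[crit].max() <= surf.max_nodes[r, c] + 1e-12

    def test_missing_node_raises(self, noisefree_records):
        partial = noisefree_records[noisefree_records["sat"] > 0]
        with pytest.raises(ValueError, match="grid nodes"):
            fit_surfaces(partial, levels=LEVELS)

    def test_json_roundtrip(self, split_pair):
        train, _ = split_pair
        surfaces = fit_surfaces(train)
        back = surfaces_from_json(surfaces_to_json(surfaces))
        for crit in surfaces:
            assert np.allclose(surfaces[crit].min_dense,
                               back[crit].min_dense)


class TestSliceRegion:
    def test_value_below_global_min_is_empty(self):
        surf = _surface(lambda s, i: 10 + 0 * s, lambda s, i: 20 + 0 * s)
        assert slice_region(5.0, surf).is_empty

    def test_constant_band_covers_domain(self):
        surf = _surface(lambda s, i: 0.0 * s, lambda s, i: 1.0 + 0 * s)
        region = slice_region(0.5, surf)
        assert region.area == pytest.approx(2500.0, rel=1e-3)

    def test_plane_slice_matches_raster_oracle(self):
        surf = _surface(lambda s, i: 1480 - 1.5 * s - 1.2 * i,
                        lambda s, i: 1500 - 1.5 * s - 1.2 * i)
        region = slice_region(1425.0, surf)
        mask, ss, ii = _raster_membership(surf, 1425.0)
        mp = region.as_multipolygon()
        from shapely import points, contains
        inside = contains(mp, points(np.stack([ss.ravel(), ii.ravel()],
                                              axis=1))).reshape(mask.shape)
        agreement = np.mean(inside == mask)
        assert agreement >= 0.99

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_random_surface_area_matches_raster(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(-1, 1) + rng.uniform(-0.05, 0.05) * LEVELS[:, None] \
            + rng.uniform(-0.05, 0.05) * LEVELS[None, :] \
            + 0.4 * rng.standard_normal((5, 5))
        width = rng.uniform(0.1, 1.0)
        surf = DecisionSurface("crx", LEVELS, base, base + width)
        value = rng.uniform(base.min(), (base + width).max())
        region = slice_region(value, surf)
        mask, _, _ = _raster_membership(surf, value, n=400)
        raster_area = mask.mean() * 2500.0
        assert region.area == pytest.approx(raster_area, abs=2500 * 0.01)


class TestIntersectionAndCentroid:
    def test_half_overlapping_squares(self):
        a = FeasibleRegion([box(0, 0, 10, 10)], ("cr1",))
        b = FeasibleRegion([box(5, 0, 15, 10)], ("cr2",))
        inter = intersect_regions([a, b])
        assert inter.area == pytest.approx(50.0)

    def test_full_domain_is_identity(self):
        a = FeasibleRegion([box(3, 4, 17, 21)], ("cr1",))
        full = FeasibleRegion([box(0, 0, 50, 50)], ("cr2",))
        inter = intersect_regions([a, full])
        assert inter.area == pytest.approx(a.area)

    def test_centroid_unit_square(self):
        region = FeasibleRegion([box(0, 0, 1, 1)])
        assert centroid_estimate(region) == pytest.approx((0.5, 0.5))

    def test_centroid_two_squares_symmetry(self):
        region = FeasibleRegion([box(5, 5, 15, 15), box(25, 25, 35, 35)])
        assert centroid_estimate(region) == pytest.approx((20.0, 20.0))

    def test_centroid_monte_carlo_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 50, size=(8, 2))
        from shapely.geometry import MultiPoint
        poly = MultiPoint(pts).convex_hull
        region = FeasibleRegion([poly])
        cx, cy = centroid_estimate(region)
        samples = rng.uniform(0, 50, size=(10 ** 6, 2))
        from shapely import contains, points
        inside = contains(poly, points(samples))
        mc = samples[inside].mean(axis=0)
        assert (cx, cy) == pytest.approx(tuple(mc), abs=0.05)

    def test_empty_centroid_raises(self):
        with pytest.raises(ValueError):
            centroid_estimate(FeasibleRegion([]))


class TestEstimate:
    def test_noise_free_exact_recovery(self, noisefree_records):
        surfaces = fit_surfaces(noisefree_records)
        sample = noisefree_records[noisefree_records["repeat"] == 1]
        for _, row in sample.iterrows():
            res = estimate(row, surfaces)
            assert res.sat_pct == pytest.approx(row["sat"], abs=1.5)
            assert res.imat_pct == pytest.approx(row["imat"], abs=1.5)

    def test_disjoint_bands_use_fallback(self):
        lo1 = _surface(lambda s, i: 0.0 * s, lambda s, i: 1.0 + 0 * s, "cr1")
        lo2 = _surface(lambda s, i: 5.0 + 0 * s, lambda s, i: 6.0 + 0 * s,
                       "cr2")
        res = estimate({"cr1": 0.5, "cr2": 0.5},
                       {"cr1": lo1, "cr2": lo2})
        assert res.fallback_used
        assert res.criteria_used < 2

    def test_monotone_refinement(self, split_pair):
        train, test = split_pair
        surfaces = fit_surfaces(train)
        row = test.iloc[10]
        regions = [slice_region(row[c], surfaces[c])
                   for c in ("cr1", "cr2", "cr3", "cr5")]
        areas = []
        for k in range(1, len(regions) + 1):
            areas.append(intersect_regions(regions[:k]).area)
        assert all(a2 <= a1 + 1e-9 for a1, a2 in zip(areas, areas[1:]))

    def test_estimate_inside_region_hull(self, split_pair):
        train, test = split_pair
        surfaces = fit_surfaces(train)
        res = estimate(test.iloc[0], surfaces)
        hull = res.region.as_multipolygon().convex_hull
        from shapely.geometry import Point
        assert hull.buffer(1e-6).contains(Point(res.sat_pct, res.imat_pct))
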