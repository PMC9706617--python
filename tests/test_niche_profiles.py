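"""Accessible areas, environmental extraction, trimming and PCA."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloniche.data_io import EnvLayer, LayerStack, OccurrenceRecord
from phyloniche.niche_profiles import (
    build_accessible_area,
    clip_area,
    extract_availability,
    extract_use,
    haversine_km,
    make_profile,
    pca_layers,
    trim_range,
)


def one_degree_global_grid() -> EnvLayer:
    return EnvLayer(
        values=np.zeros((180, 360)),
        nodata_mask=np.zeros((180, 360), dtype=bool),
        extent=(-180.0, 180.0, -90.0, 90.0),
        resolution=60.0,
        variable_id="temperature",
    )


def brute_force_buffer(lon, lat, grid, buffer_km):
    """Per-cell scalar haversine scan — the reference for buffering."""
    mask = np.zeros(grid.shape, dtype=bool)
    lats = grid.lat_centers
    lons = grid.lon_centers
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            p1, p2 = math.radians(lat), math.radians(lats[i])
            dphi = p2 - p1
            dlmb = math.radians(lons[j] - lon)
            h = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
            d = 2 * 6371.0 * math.asin(math.sqrt(h))
            mask[i, j] = d <= buffer_km
    return mask


class TestBuildAccessibleArea:
    def test_zero_buffer_is_exactly_occupied_cells(self, flat_layer):
        recs = [OccurrenceRecord("A", 1.5, 2.5), OccurrenceRecord("A", 7.2, 8.9)]
        area = build_accessible_area(recs, flat_layer, buffer_km=0.0)
        assert area.n_cells == 2
        assert area.mask[flat_layer.cell_of(1.5, 2.5)]
        assert area.mask[flat_layer.cell_of(7.2, 8.9)]

    def test_500km_buffer_matches_brute_force_haversine(self):
        grid = one_degree_global_grid()
        recs = [OccurrenceRecord("A", 0.0, 0.0)]
        area = build_accessible_area(recs, grid, buffer_km=500.0)
        expected = brute_force_buffer(0.0, 0.0, grid, 500.0)
        expected[grid.cell_of(0.0, 0.0)] = True
        assert np.array_equal(area.mask, expected)

    def test_union_of_overlapping_buffers(self, flat_layer):
        recs = [OccurrenceRecord("A", 4.5, 4.5), OccurrenceRecord("A", 5.5, 4.5)]
        a1 = build_accessible_area(recs[:1], flat_layer, 200.0)
        a2 = build_accessible_area(recs[1:], flat_layer, 200.0)
        both = build_accessible_area(recs, flat_layer, 200.0)
        assert np.array_equal(both.mask, a1.mask | a2.mask)
        assert both.n_cells <= a1.n_cells + a2.n_cells

    def test_monotone_in_buffer_distance(self, flat_layer):
        recs = [OccurrenceRecord("A", 5.0, 5.0)]
        small = build_accessible_area(recs, flat_layer, 150.0)
        large = build_accessible_area(recs, flat_layer, 400.0)
        assert np.all(large.mask[small.mask])

    def test_no_record_inside_extent_is_error(self, flat_layer):
        with pytest.raises(ValueError, match="extent"):
            build_accessible_area([OccurrenceRecord("A", 50.0, 50.0)], flat_layer, 100.0)

    def test_nodata_cells_excluded(self, flat_layer):
        flat_layer.nodata_mask[0, :] = True
        recs = [OccurrenceRecord("A", 5.0, 5.0)]
        area = build_accessible_area(recs, flat_layer, 2000.0)
        assert not area.mask[0, :].any()


class TestClipArea:
    def _area(self, layer):
        return build_accessible_area([OccurrenceRecord("A", 5.0, 5.0)], layer, 400.0)

    def test_all_true_keep_mask_is_identity(self, flat_layer):
        area = self._area(flat_layer)
        clipped = clip_area(area, np.ones(flat_layer.shape, dtype=bool))
        assert np.array_equal(clipped.mask, area.mask)

    def test_removes_cells_without_occurrences(self, flat_layer):
        area = self._area(flat_layer)
        keep = np.ones(flat_layer.shape, dtype=bool)
        keep[:, 0] = False  # far column, no occurrences
        clipped = clip_area(area, keep)
        assert not clipped.mask[:, 0].any()
        assert clipped.mask[flat_layer.cell_of(5.0, 5.0)]

    def test_refuses_to_drop_occupied_cell(self, flat_layer):
        area = self._area(flat_layer)
        keep = np.ones(flat_layer.shape, dtype=bool)
        keep[flat_layer.cell_of(5.0, 5.0)] = False
        with pytest.raises(ValueError, match="occupied"):
            clip_area(area, keep)
        clipped = clip_area(area, keep, allow_occ_loss=True)
        assert not clipped.mask[flat_layer.cell_of(5.0, 5.0)]


class TestExtraction:
    def test_use_on_constant_layer(self, flat_layer):
        recs = [OccurrenceRecord("A", 1.0, 1.0), OccurrenceRecord("A", 2.0, 2.0)]
        values, skipped = extract_use(recs, flat_layer)
        assert values.tolist() == [5.0, 5.0] and skipped == 0

    def test_occurrence_on_nodata_skipped_and_counted(self, flat_layer):
        flat_layer.nodata_mask[flat_layer.cell_of(1.0, 1.0)] = True
        recs = [OccurrenceRecord("A", 1.0, 1.0), OccurrenceRecord("A", 2.0, 2.0)]
        values, skipped = extract_use(recs, flat_layer)
        assert len(values) == 1 and skipped == 1

    def test_all_occurrences_on_nodata_is_error(self, flat_layer):
        flat_layer.nodata_mask[:] = True
        with pytest.raises(ValueError, match="nodata"):
            extract_use([OccurrenceRecord("A", 1.0, 1.0)], flat_layer)

    def test_availability_lists_mask_cell_values(self, flat_layer):
        flat_layer.values[0, 0], flat_layer.values[0, 1], flat_layer.values[0, 2] = 1, 2, 3
        area = build_accessible_area([OccurrenceRecord("A", 0.5, 9.5)], flat_layer, 0.0)
        area.mask[0, :3] = True
        assert sorted(extract_availability(area, flat_layer)) == [1.0, 2.0, 3.0]


class TestTrimRange:
    def test_constant_values(self):
        assert trim_range([5, 5, 5], 0.95) == (5.0, 5.0)

    def test_matches_percentile_oracle_on_1_to_1000(self):
        values = np.arange(1, 1001, dtype=float)
        lo, hi = trim_range(values, 0.95)
        # linear-interpolation percentile computed directly
        assert lo == pytest.approx(np.percentile(values, 2.5))
        assert hi == pytest.approx(np.percentile(values, 97.5))
        assert lo == pytest.approx(1 + 0.025 * 999)
        assert hi == pytest.approx(1 + 0.975 * 999)

    def test_level_one_returns_min_max(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal(57)
        assert trim_range(values, 1.0) == (values.min(), values.max())

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            trim_range([], 0.95)

    @settings(derandomize=True, max_examples=50)
    @given(
        values=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60),
        l1=st.floats(0.05, 0.95),
        l2=st.floats(0.05, 0.95),
    )
    def test_stricter_level_gives_nested_interval(self, values, l1, l2):
        lo_narrow, hi_narrow = trim_range(values, min(l1, l2))
        lo_wide, hi_wide = trim_range(values, max(l1, l2))
        assert lo_wide <= lo_narrow + 1e-9 and hi_narrow <= hi_wide + 1e-9


def _stack_from(arrays):
    nrows, ncols = arrays[0].shape
    extent = (0.0, float(ncols), 0.0, float(nrows))
    layers = [
        EnvLayer(a, np.zeros(a.shape, dtype=bool), extent, 60.0, f"v{i}")
        for i, a in enumerate(arrays)
    ]
    return LayerStack(layers)


class TestPcaLayers:
    def test_single_layer_k1_is_zscore_up_to_sign(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((10, 10))
        stack = _stack_from([a])
        out, ratios = pca_layers(stack, k=1)
        z = (a - a.mean()) / a.std()
        assert ratios[0] == pytest.approx(1.0)
        assert np.allclose(np.abs(out[0].values), np.abs(z))

    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((10, 10))
        stack = _stack_from([a, 3.0 * a + 2.0])
        out, ratios = pca_layers(stack, k=2)
        assert ratios[0] == pytest.approx(1.0, abs=1e-12)
        assert ratios[1] == pytest.approx(0.0, abs=1e-12)

    def test_variance_fractions_match_eigendecomposition(self):
        rng = np.random.default_rng(2)
        arrays = [rng.standard_normal((12, 9)) for _ in range(3)]
        arrays[2] += 0.7 * arrays[0]
        stack = _stack_from(arrays)
        _, ratios = pca_layers(stack, k=2)
        X = np.column_stack([a.ravel() for a in arrays])
        corr = np.corrcoef(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert np.allclose(ratios, (eig / eig.sum())[:2])

    def test_components_uncorrelated(self):
        rng = np.random.default_rng(3)
        arrays = [rng.standard_normal((15, 15)) for _ in range(4)]
        stack = _stack_from(arrays)
        out, _ = pca_layers(stack, k=3)
        scores = np.column_stack([lyr.values.ravel() for lyr in out])
        corr = np.corrcoef(scores, rowvar=False)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 1e-8)

    def test_constant_layer_rejected(self):
        stack = _stack_from([np.ones((10, 10)), np.arange(100.0).reshape(10, 10)])
        with pytest.raises(ValueError, match="constant"):
            pca_layers(stack, k=1)


class TestMakeProfile:
    def test_basic_profile(self):
        p = make_profile("A", "t", [10, 12, 20], np.arange(31.0), trim_level=1.0)
        assert p.used_range == (10.0, 20.0)
        assert p.available_range == (0.0, 30.0)

    def test_use_clipped_into_availability_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            p = make_profile("A", "t", [-5.0, 10.0], [0.0, 30.0], trim_level=1.0)
        assert p.used_range[0] == 0.0

    def test_single_occurrence_degenerate_range(self):
        p = make_profile("A", "t", [7.0], [0.0, 30.0], trim_level=0.95)
        assert p.used_range == (7.0, 7.0)

    def test_disjoint_use_and_availability_is_error(self):
        with pytest.raises(ValueError, match="disjoint"):
            make_profile("A", "t", [100.0, 110.0], [0.0, 30.0], trim_level=1.0)

    def test_used_subset_of_available_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            avail = rng.normal(size=40)
            use = rng.choice(avail, size=10)
            p = make_profile("A", "t", use, avail, trim_level=0.9)
            assert p.available_range[0] <= p.used_range[0]
            assert p.used_range[1] <= p.available_range[1]
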