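import math

import numpy as np
import pytest

from recogmem import spatial as sp
from recogmem.behavior import ZoneOccupancy, assign_zones

from conftest import make_track


class TestOccupancyMap:
    def test_single_bin_accumulates_duration(self, radial_layout):
        track = make_track(np.tile([10.0, 10.0], (250, 1)), fps=25)
        hm = sp.occupancy_map(track, radial_layout)
        assert hm.grid[0, 0] == pytest.approx(10.0)
        assert np.count_nonzero(hm.grid) == 1

    def test_mass_conservation_is_exact(self, radial_layout):
        rng = np.random.default_rng(5)
        track = make_track(rng.uniform(0, 500, (999, 2)), fps=60)
        hm = sp.occupancy_map(track, radial_layout)
        assert hm.total == pytest.approx(999 / 60, abs=1e-9)

    def test_uniform_positions_fill_bins_uniformly(self, radial_layout):
        rng = np.random.default_rng(0)
        n = 100_000
        track = make_track(rng.uniform(0, 500, (n, 2)), fps=60)
        hm = sp.occupancy_map(track, radial_layout)
        counts = hm.grid * 60  # back to frame counts
        p = 1 / 100  # 10x10 bins
        sd = math.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 4 * sd)

    def test_point_on_right_edge_falls_in_last_bin(self, radial_layout):
        track = make_track([[500.0, 500.0]], fps=25)
        hm = sp.occupancy_map(track, radial_layout)
        assert hm.grid[-1, -1] > 0
        assert hm.n_clamped == 0

    def test_stray_point_clamped_and_flagged(self, radial_layout):
        track = make_track([[500.8, 250.0]], fps=25)
        hm = sp.occupancy_map(track, radial_layout)
        assert hm.n_clamped == 1
        assert hm.grid[5, 9] > 0


class TestEventMap:
    def test_no_events_gives_zero_grid(self, radial_layout):
        hm = sp.event_map(np.empty((0, 2)), radial_layout)
        assert hm.total == 0.0

    def test_counts_in_single_bin(self, radial_layout):
        pos = np.tile([30.0, 30.0], (12, 1))
        hm = sp.event_map(pos, radial_layout)
        assert hm.grid[0, 0] == 12 and hm.total == 12


class TestColumnCorrelation:
    def test_proportional_maps_give_unit_correlation(self, radial_layout):
        rng = np.random.default_rng(2)
        grid = rng.random((10, 10))
        a = sp.HeatMap(grid=grid, bin_px=50.0)
        b = sp.HeatMap(grid=3.0 * grid, bin_px=50.0, units="counts")
        prof = sp.column_correlation(a, b)
        assert prof.n_valid == 10
        np.testing.assert_allclose(prof.valid, 1.0, atol=1e-12)

    def test_zero_variance_column_is_undefined(self):
        grid = np.ones((5, 3))
        grid[:, 1] = [1, 2, 3, 4, 5]
        a = sp.HeatMap(grid=grid, bin_px=50.0)
        b = sp.HeatMap(grid=grid.copy(), bin_px=50.0)
        prof = sp.column_correlation(a, b)
        assert np.isnan(prof.r[0]) and np.isnan(prof.r[2])
        assert prof.n_valid == 1

    def test_shape_mismatch_rejected(self):
        a = sp.HeatMap(grid=np.ones((4, 4)), bin_px=50.0)
        b = sp.HeatMap(grid=np.ones((5, 4)), bin_px=50.0)
        with pytest.raises(ValueError):
            sp.column_correlation(a, b)

    def test_symmetry_and_positive_scale_invariance(self):
        rng = np.random.default_rng(3)
        g1, g2 = rng.random((8, 8)), rng.random((8, 8))
        a, b = sp.HeatMap(grid=g1, bin_px=50.0), sp.HeatMap(grid=g2, bin_px=50.0)
        ab = sp.column_correlation(a, b).r
        ba = sp.column_correlation(b, a).r
        scaled = sp.column_correlation(sp.HeatMap(grid=7.5 * g1, bin_px=50.0), b).r
        np.testing.assert_allclose(ab, ba, atol=1e-12)
        np.testing.assert_allclose(ab, scaled, atol=1e-12)

    def test_row_permutation_destroys_correlation(self):
        # permuting the rows of one map should leave only chance-level r
        rng = np.random.default_rng(4)
        medians = []
        for _ in range(100):
            g = rng.random((30, 8))
            a = sp.HeatMap(grid=g, bin_px=50.0)
            b = sp.HeatMap(grid=g[rng.permutation(30)], bin_px=50.0)
            medians.append(sp.column_correlation(a, b).median_r)
        assert abs(float(np.median(medians))) < 0.3


class TestZoneEventRatio:
    def _occ(self):
        labels = np.array(["a"] * 40 + ["b"] * 40 + ["none"] * 20)
        return ZoneOccupancy(labels=labels, zone_time_s={"a": 40 / 25, "b": 40 / 25}, fps=25.0)

    def test_simple_ratio(self):
        frames = np.concatenate([np.arange(30), 40 + np.arange(15)])
        assert sp.zone_event_ratio(frames, self._occ(), "a", "b") == pytest.approx(2.0)

    def test_zero_over_zero_is_undefined(self):
        frames = np.array([85, 90])  # all in "none"
        assert math.isnan(sp.zone_event_ratio(frames, self._occ(), "a", "b"))

    def test_positive_over_zero_is_infinite(self):
        frames = np.arange(10)
        assert math.isinf(sp.zone_event_ratio(frames, self._occ(), "a", "b"))

    def test_unknown_zone_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            sp.zone_event_ratio(np.array([0]), self._occ(), "a", "ghost")


class TestRatioIndexCorrelation:
    def test_affine_relation_gives_unit_r(self):
        pairs = [(1.0, 0.5), (2.0, 0.6), (3.0, 0.7), (4.0, 0.8)]
        r, p, n, excl = sp.ratio_index_correlation(pairs)
        assert r == pytest.approx(1.0)
        assert n == 4 and excl == 0

    def test_markers_are_excluded_not_coerced(self):
        pairs = [(1.0, 0.5), (2.0, 0.6), (3.0, 0.7), (math.inf, 0.9), (math.nan, 0.2)]
        r, _, n, excl = sp.ratio_index_correlation(pairs)
        assert n == 3 and excl == 2
        assert r == pytest.approx(1.0)

    def test_too_few_finite_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 finite"):
            sp.ratio_index_correlation([(1.0, 0.5), (math.inf, 0.6), (2.0, None)])


class TestNoseDistanceVector:
    def test_three_four_five(self):
        track = make_track([[3.0, 4.0], [0.0, 0.0]])
        d = sp.nose_distance_vector(track, (0.0, 0.0))
        np.testing.assert_allclose(d, [5.0, 0.0])

    def test_centimeter_conversion(self):
        track = make_track([[30.0, 40.0]])
        d = sp.nose_distance_vector(track, (0.0, 0.0), px_per_cm=10.0)
        assert d[0] == pytest.approx(5.0)

    def test_consistent_with_radial_zone_assignment(self, radial_layout):
        rng = np.random.default_rng(6)
        track = make_track(rng.uniform(0, 500, (500, 2)))
        occ = assign_zones(track, radial_layout)
        for ch in radial_layout.chambers:
            d = sp.nose_distance_vector(track, ch.center_xy)
            other = [c for c in radial_layout.chambers if c.label != ch.label][0]
            d_other = sp.nose_distance_vector(track, other.center_xy)
            in_zone = (d < radial_layout.radial_radius_px) & (d < d_other)
            np.testing.assert_array_equal(in_zone, occ.labels == ch.label)
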