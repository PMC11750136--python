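import math

import numpy as np
import pytest

from recogmem import synthetic as syn
from recogmem.behavior import assign_zones, discrimination_index
from recogmem.io_formats import ArenaLayout, Chamber


class TestDeterminism:
    def test_trajectory_bit_identical_under_seed(self, radial_layout):
        m = syn.TrajectoryModel(attraction_gains={"novel": 1.0})
        a = syn.simulate_trajectory(m, radial_layout, 10.0, seed=42)
        b = syn.simulate_trajectory(m, radial_layout, 10.0, seed=42)
        np.testing.assert_array_equal(a.nose_xy, b.nose_xy)

    def test_photometry_bit_identical_under_seed(self, radial_layout):
        m = syn.TrajectoryModel()
        track = syn.simulate_trajectory(m, radial_layout, 20.0, seed=0)
        cm = syn.CouplingModel(baseline_rate_hz=0.5)
        s1, e1 = syn.simulate_photometry(track, radial_layout, cm, seed=7)
        s2, e2 = syn.simulate_photometry(track, radial_layout, cm, seed=7)
        np.testing.assert_array_equal(s1.f470, s2.f470)
        np.testing.assert_array_equal(e1, e2)

    def test_cellcounts_identical_under_seed(self):
        t1 = syn.simulate_cellcounts({"EN": 250.0, "BLA": 120.0}, 5.0, 5, seed=3)
        t2 = syn.simulate_cellcounts({"EN": 250.0, "BLA": 120.0}, 5.0, 5, seed=3)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_sweeps_identical_under_seed(self):
        a = syn.simulate_ephys_sweeps(6, 5.0, (0.2, -40.0, 0.02), seed=9)
        b = syn.simulate_ephys_sweeps(6, 5.0, (0.2, -40.0, 0.02), seed=9)
        np.testing.assert_array_equal(a.sweeps, b.sweeps)

    def test_pixelchange_identical_under_seed(self):
        a = syn.simulate_pixelchange([(2.0, 5.0)], 20.0, seed=4)
        b = syn.simulate_pixelchange([(2.0, 5.0)], 20.0, seed=4)
        np.testing.assert_array_equal(a, b)


class TestTrajectory:
    def test_zero_duration_rejected(self, radial_layout):
        with pytest.raises(ValueError):
            syn.simulate_trajectory(syn.TrajectoryModel(), radial_layout, 0.0)

    def test_stays_inside_arena(self, radial_layout):
        m = syn.TrajectoryModel(step_sd_px=40.0, attraction_gains={"novel": 3.0})
        track = syn.simulate_trajectory(m, radial_layout, 60.0, seed=1)
        assert np.all(track.nose_xy >= 0.0)
        assert np.all(track.nose_xy[:, 0] <= 500.0)
        assert np.all(track.nose_xy[:, 1] <= 500.0)

    def test_unbiased_walk_occupancy_proportional_to_area(self, radial_layout):
        # big steps decorrelate frames; compare zone time with the area ratio
        m = syn.TrajectoryModel(step_sd_px=150.0)
        track = syn.simulate_trajectory(m, radial_layout, 10_000 / 60.0, seed=2)
        occ = assign_zones(track, radial_layout)
        in_any = sum(occ.zone_time_s.values()) / track.duration_s
        p = 2 * math.pi * 100**2 / 500**2  # two 100 px discs in a 500 px arena
        # conservative effective sample size for residual autocorrelation
        n_eff = 10_000 / 4
        sd = math.sqrt(p * (1 - p) / n_eff)
        assert abs(in_any - p) < 3 * sd

    def test_doubled_gain_biases_discrimination_above_chance(self, radial_layout):
        dis = []
        for seed in range(20):
            m = syn.TrajectoryModel(attraction_gains={"novel": 2.0, "familiar": 1.0})
            track = syn.simulate_trajectory(m, radial_layout, 300.0, seed=seed)
            occ = assign_zones(track, radial_layout)
            dis.append(discrimination_index(occ.time_in("novel"), occ.time_in("familiar")))
        assert float(np.mean(dis)) > 0.5

    def test_occupancy_monotone_in_gain(self, radial_layout):
        times = []
        for gain in (0.0, 1.0, 3.0):
            m = syn.TrajectoryModel(attraction_gains={"novel": gain, "familiar": 1.0})
            track = syn.simulate_trajectory(m, radial_layout, 300.0, seed=11)
            occ = assign_zones(track, radial_layout)
            times.append(occ.time_in("novel"))
        assert times[0] < times[1] < times[2]


class TestPhotometrySim:
    def test_zero_rate_means_no_events(self, radial_layout):
        track = syn.simulate_trajectory(syn.TrajectoryModel(), radial_layout, 30.0, seed=0)
        model = syn.CouplingModel(baseline_rate_hz=0.0)
        sig, events = syn.simulate_photometry(track, radial_layout, model, seed=1)
        assert len(events) == 0
        assert abs(sig.f470.std() - model.noise_sd) < 0.05

    def test_event_count_matches_poisson_mean(self, radial_layout):
        # rate 0.2/s everywhere for 300 s: expected 60 events
        track = syn.simulate_trajectory(syn.TrajectoryModel(), radial_layout, 300.0, seed=3)
        model = syn.CouplingModel(baseline_rate_hz=0.2)
        counts = [
            len(syn.simulate_photometry(track, radial_layout, model, seed=s)[1])
            for s in range(50)
        ]
        assert abs(float(np.mean(counts)) - 60.0) < 2 * math.sqrt(60.0)

    def test_event_times_strictly_increasing_and_in_window(self, radial_layout):
        track = syn.simulate_trajectory(syn.TrajectoryModel(), radial_layout, 60.0, seed=4)
        model = syn.CouplingModel(baseline_rate_hz=1.0)
        _, events = syn.simulate_photometry(track, radial_layout, model, seed=5)
        assert np.all(np.diff(events) > 0)
        assert events[0] >= 0.0 and events[-1] <= track.duration_s

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError):
            syn.CouplingModel(tau_rise_s=1.0, tau_decay_s=0.5)


class TestPixelChange:
    def test_no_bouts_means_no_freezing(self):
        from recogmem.freezing import detect_freezing

        series = syn.simulate_pixelchange([], 300.0, seed=0)
        assert detect_freezing(series, fps=25.0).total_frozen_s == 0.0

    def test_percent_freezing_matches_construction(self):
        from recogmem.freezing import detect_freezing, percent_freezing
        from recogmem.io_formats import PhaseWindow

        bouts = [(10.0, 20.0), (100.0, 120.0)]  # 30 s of 300 s
        series = syn.simulate_pixelchange(bouts, 300.0, seed=1)
        res = detect_freezing(series, fps=25.0)
        pct = percent_freezing(res, [PhaseWindow(label="all", start_s=0, end_s=300)])
        assert pct["all"] == pytest.approx(10.0, abs=1.0)

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            syn.simulate_pixelchange([(1.0, 5.0), (4.0, 8.0)], 20.0)

    def test_misplaced_level_parameters_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_pixelchange([], 10.0, moving_level=0.0005)


class TestCellCounts:
    def test_poisson_limit_mean(self):
        n = 200
        table = syn.simulate_cellcounts({"EN": 250.0}, math.inf, n, seed=0)
        assert abs(table.counts.mean() - 250.0) < 3 * math.sqrt(250.0 / n)

    def test_table_shape_matches_reference_design(self):
        table = syn.simulate_cellcounts(
            {"EN": 250.0, "BLA": 140.0, "SP (lateral)": 45.0, "SP (medial)": 110.0},
            dispersion=8.0, n_subjects=5, seed=2,
        )
        assert table.counts.shape == (4, 5)
        assert table.regions == ("EN", "BLA", "SP (lateral)", "SP (medial)")

    def test_overdispersion_exceeds_poisson(self):
        t = syn.simulate_cellcounts({"EN": 200.0}, dispersion=2.0, n_subjects=4000, seed=3)
        assert t.counts.var() > 2.0 * t.counts.mean()


class TestEphysSweeps:
    def test_zero_peak_is_zero_response(self):
        from recogmem.ephys import classify_response

        ss = syn.simulate_ephys_sweeps(6, 5.0, (0.2, 0.0, 0.02), fs=2000.0, seed=0)
        assert not classify_response(ss, criterion_on="mean").is_response

    def test_ten_sigma_peak_is_detected(self):
        from recogmem.ephys import classify_response

        ss = syn.simulate_ephys_sweeps(6, 5.0, (0.2, -50.0, 0.02), fs=2000.0, seed=1)
        assert classify_response(ss).is_response


class TestCohort:
    def test_cohort_is_reproducible_and_heterogeneous(self):
        c1 = syn.simulate_cohort(seed=5, n_subjects=3, duration_s=30.0)
        c2 = syn.simulate_cohort(seed=5, n_subjects=3, duration_s=30.0)
        gains1 = [s.trajectory_model.attraction_gains["novel"] for s in c1]
        gains2 = [s.trajectory_model.attraction_gains["novel"] for s in c2]
        assert gains1 == gains2
        assert len(set(gains1)) == 3
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.track.nose_xy, b.track.nose_xy)
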