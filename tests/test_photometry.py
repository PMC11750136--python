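import numpy as np
import pytest

from recogmem import photometry as ph
from recogmem.io_formats import PhotometrySignal

from conftest import make_track


def make_signal(f470, fs=120.0, f415=None):
    f470 = np.asarray(f470, dtype=float)
    n = len(f470)
    f415 = np.zeros(n) if f415 is None else np.asarray(f415, dtype=float)
    return PhotometrySignal(time_s=np.arange(n) / fs, f470=f470, f415=f415, fs=fs)


def naive_rising_edges(z, threshold):
    """Reference O(n) scan: count i>=1 with z[i-1] <= thr < z[i]."""
    count = 0
    for i in range(1, len(z)):
        if z[i - 1] <= threshold < z[i]:
            count += 1
    return count


class TestLowpass:
    def test_constant_signal_unchanged(self):
        sig = make_signal(np.full(1000, 3.7))
        out = ph.lowpass(sig)
        np.testing.assert_allclose(out.f470, 3.7, atol=1e-9)

    def test_60hz_component_attenuated(self):
        t = np.arange(4800) / 240.0
        sig = make_signal(np.sin(2 * np.pi * 60 * t), fs=240.0)
        out = ph.lowpass(sig, cutoff_hz=40.0)
        mid = slice(1000, 3800)  # avoid filter edges
        assert np.abs(out.f470[mid]).max() < 0.5

    def test_passband_tone_preserved(self):
        t = np.arange(4800) / 240.0
        sig = make_signal(np.sin(2 * np.pi * 5 * t), fs=240.0)
        out = ph.lowpass(sig, cutoff_hz=40.0)
        mid = slice(1000, 3800)
        assert np.abs(out.f470[mid]).max() == pytest.approx(1.0, rel=0.02)

    def test_nyquist_violation_rejected(self):
        sig = make_signal(np.zeros(100), fs=60.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ph.lowpass(sig, cutoff_hz=40.0)


class TestZscore:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        sig = make_signal(rng.normal(5.0, 2.0, 5000))
        out = ph.zscore(sig)
        assert out.z.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_constant_trace_rejected(self):
        sig = make_signal(np.full(200, 2.0))
        with pytest.raises(ValueError, match="variance"):
            ph.zscore(sig)

    def test_transient_four_baseline_sds_peaks_near_four(self):
        rng = np.random.default_rng(1)
        n = 12000
        base = rng.normal(0.0, 1.0, n)
        base[6000:6010] += 4.0  # brief 4-sigma transient
        sig = make_signal(base)
        out = ph.zscore(sig, baseline_window_s=(0.0, 40.0))
        assert out.z[6000:6010].mean() == pytest.approx(4.0, abs=1.0)

    def test_short_baseline_window_rejected(self):
        sig = make_signal(np.random.default_rng(2).normal(size=2400))
        with pytest.raises(ValueError, match="10 s"):
            ph.zscore(sig, baseline_window_s=(0.0, 5.0))

    def test_isosbestic_regression_removes_shared_motion(self):
        rng = np.random.default_rng(3)
        motion = rng.normal(0.0, 1.0, 6000)
        f415 = motion + rng.normal(0.0, 0.01, 6000)
        f470 = 2.0 * motion + rng.normal(0.0, 0.01, 6000)
        sig = make_signal(f470, f415=f415)
        out = ph.zscore(sig, regress_isosbestic=True)
        # after regression the residual is the small independent noise
        assert np.corrcoef(out.z, motion)[0, 1] ** 2 < 0.1


class TestResample:
    def test_output_grid_aligned_to_zero(self):
        sig = make_signal(np.random.default_rng(0).normal(size=1200), fs=120.0)
        out = ph.resample_to(sig, 60.0)
        np.testing.assert_allclose(out.time_s, np.arange(len(out.time_s)) / 60.0)

    def test_constant_preserved(self):
        sig = make_signal(np.full(1200, 2.5), fs=120.0)
        out = ph.resample_to(sig, 60.0)
        np.testing.assert_allclose(out.f470, 2.5, atol=1e-9)

    def test_passband_amplitude_preserved(self):
        t = np.arange(2400) / 120.0
        sig = make_signal(np.sin(2 * np.pi * 1.0 * t), fs=120.0)
        out = ph.resample_to(sig, 60.0)
        mid = slice(240, -240)
        assert np.abs(out.f470[mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_upsampling_refused(self):
        sig = make_signal(np.zeros(100), fs=60.0)
        with pytest.raises(ValueError, match="down-samples"):
            ph.resample_to(sig, 120.0)

    def test_lowpass_and_resample_commute_for_bandlimited_input(self):
        t = np.arange(4800) / 240.0
        x = np.sin(2 * np.pi * 2 * t) + 0.5 * np.sin(2 * np.pi * 7 * t)
        sig = make_signal(x, fs=240.0)
        a = ph.resample_to(ph.lowpass(sig), 60.0).f470
        b = ph.lowpass(ph.resample_to(sig, 60.0), cutoff_hz=25.0)
        c = ph.resample_to(ph.lowpass(sig, cutoff_hz=25.0), 60.0).f470
        mid = slice(120, -120)
        rms = np.sqrt(np.mean((b.f470[mid] - c[mid]) ** 2)) / np.sqrt(np.mean(c[mid] ** 2))
        assert rms < 0.01


class TestDetectEvents:
    def _z_signal(self, z, fs=60.0):
        sig = make_signal(np.zeros(len(z)), fs=fs)
        sig.z = np.asarray(z, dtype=float)
        return sig

    def test_all_subthreshold_yields_no_events(self):
        sig = self._z_signal(np.zeros(100))
        assert ph.detect_events(sig).n_events == 0

    def test_boxcar_excursion_is_one_event(self):
        z = np.zeros(100)
        z[40:70] = 5.0
        assert ph.detect_events(self._z_signal(z)).n_events == 1

    def test_seven_separated_excursions(self):
        z = np.zeros(700)
        for k in range(7):
            z[50 + 90 * k : 60 + 90 * k] = 3.0
        ev = ph.detect_events(self._z_signal(z))
        assert ev.n_events == 7 == naive_rising_edges(z, 2.58)

    def test_matches_naive_scan_on_random_traces(self):
        for seed in range(200):
            rng = np.random.default_rng(seed)
            z = rng.normal(0, 1.5, 500)
            ev = ph.detect_events(self._z_signal(z))
            assert ev.n_events == naive_rising_edges(z, 2.58)

    def test_trace_starting_above_threshold_needs_a_crossing(self):
        z = np.full(50, 5.0)
        assert ph.detect_events(self._z_signal(z)).n_events == 0

    def test_refractory_suppresses_close_crossings(self):
        z = np.zeros(300)
        z[50] = z[60] = z[200] = 5.0  # crossings at 50, 60 (0.17 s apart), 200
        ev = ph.detect_events(self._z_signal(z, fs=60.0), refractory_s=1.0)
        assert ev.n_events == 2

    def test_hysteresis_ignores_chatter_until_rearm(self):
        z = np.zeros(300)
        z[50] = 5.0
        z[51:80] = 2.0  # hovers above re-arm, chatters across threshold
        z[60] = 5.0
        z[100:105] = 0.0  # falls below re-arm
        z[150] = 5.0
        ev = ph.detect_events(self._z_signal(z), rearm_z=1.0)
        assert list(ev.sample_index) == [50, 150]

    def test_event_count_invariant_to_amplitude_rescaling(self):
        rng = np.random.default_rng(11)
        f = rng.normal(0, 1, 6000)
        f[2000:2005] += 6
        f[4000:4005] += 6
        n1 = ph.detect_events(ph.zscore(make_signal(f))).n_events
        n2 = ph.detect_events(ph.zscore(make_signal(5.0 * f + 100.0))).n_events
        assert n1 == n2


class TestDetectionRecovery:
    """Precision of the full conditioning/detection chain on simulated
    sessions with known ground-truth event times."""

    def test_detected_events_match_ground_truth_closely(self):
        from recogmem import synthetic as syn

        offsets = []
        for seed in range(5):
            sess = syn.simulate_discrimination_session(seed=seed, duration_s=300.0)
            cond = ph.condition(sess.signal)
            ev = ph.detect_events(cond, rearm_z=1.0)
            true = sess.true_event_times
            assert ev.n_events > 0
            offsets.extend(
                float(np.min(np.abs(true - t))) for t in ev.time_s
            )
        offsets = np.asarray(offsets)
        # nearly every detected event sits within 0.25 s of a real transient
        # (0.25 s of walking covers well under one 50 px spatial bin)
        assert np.mean(offsets <= 0.25) >= 0.95
        # detection lags onset by the kernel's rise-to-threshold time
        assert np.median(offsets) <= 10 / 60.0


class TestEventsToPositions:
    def test_event_maps_to_nearest_frame(self):
        xy = np.arange(240, dtype=float).reshape(-1, 2)  # 120 frames at 60 fps
        track = make_track(xy, fps=60)
        ev = ph.EventTrain(time_s=np.array([1.0]), sample_index=np.array([60]), threshold=2.58)
        pos = ph.events_to_positions(ev, track)
        np.testing.assert_allclose(pos[0], xy[60])

    def test_event_beyond_track_end_rejected(self):
        track = make_track(np.zeros((60, 2)), fps=60)
        ev = ph.EventTrain(time_s=np.array([5.0]), sample_index=np.array([300]), threshold=2.58)
        with pytest.raises(ValueError, match="outside"):
            ph.events_to_positions(ev, track)

    def test_fractional_times_round_to_nearest_frame(self):
        xy = np.arange(240, dtype=float).reshape(-1, 2)
        track = make_track(xy, fps=60)
        ev = ph.EventTrain(
            time_s=np.array([0.3 / 60, 1.0 + 0.4 / 60]),
            sample_index=np.array([0, 60]),
            threshold=2.58,
        )
        pos = ph.events_to_positions(ev, track)
        np.testing.assert_allclose(pos, xy[[0, 60]])
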