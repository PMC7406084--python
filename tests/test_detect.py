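import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from reefscape import CalibratedSegment
from reefscape.detect import (
    count_pulses,
    design_bandpass,
    detect,
    fish_config,
    shrimp_config,
    teager_kaiser,
    validate,
)

T0 = pd.Timestamp("2018-09-20")


def brute_force_count(energy: np.ndarray, threshold: float, min_gap: float) -> int:
    """Independent oracle: naive scan for supra-threshold energy peaks,
    then a sample-by-sample greedy refractory count."""
    n = len(energy)
    peaks = []
    for i in range(n):
        if energy[i] <= threshold:
            continue
        left_ok = i == 0 or energy[i] > energy[i - 1]
        right_ok = i == n - 1 or energy[i] >= energy[i + 1]
        if left_ok and right_ok:
            peaks.append(i)
    count, last = 0, None
    for p in peaks:
        if last is None or p - last >= min_gap:
            count += 1
            last = p
    return count


class TestBandpassDesign:
    def test_fish_filter_response(self):
        taps = design_bandpass(100, 800, 20, 2000)
        w, h = signal.freqz(taps, worN=8192, fs=2000)
        gain_db = 20 * np.log10(np.abs(h) + 1e-12)
        assert abs(gain_db[np.argmin(np.abs(w - 450))]) <= 3.0
        assert gain_db[np.argmin(np.abs(w - 20))] < -10.0
        assert gain_db[np.argmin(np.abs(w - 990))] < -10.0

    def test_tap_count_is_order_plus_one(self):
        assert len(design_bandpass(100, 800, 20, 2000)) == 21
        assert len(design_bandpass(4000, 9000, 34, 48000)) == 35

    def test_shrimp_filter_passes_6khz_rejects_500hz(self):
        taps = design_bandpass(4000, 9000, 20, 48000)
        w, h = signal.freqz(taps, worN=8192, fs=48000)
        g = np.abs(h)
        assert g[np.argmin(np.abs(w - 6000))] >= 0.7
        assert g[np.argmin(np.abs(w - 500))] < g[np.argmin(np.abs(w - 6000))]

    def test_infeasible_band_rejected(self):
        with pytest.raises(ValueError):
            design_bandpass(800, 100, 20, 2000)


class TestTeagerKaiser:
    def test_constant_series_gives_zero(self):
        psi = teager_kaiser(np.full(50, 3.7))
        np.testing.assert_allclose(psi, 0.0, atol=1e-12)

    def test_sinusoid_closed_form(self):
        # psi of A sin(w n) is the constant A^2 sin^2(w)
        a, w = 2.0, 0.1
        x = a * np.sin(w * np.arange(1000))
        psi = teager_kaiser(x)[1:-1]
        expected = a**2 * np.sin(w) ** 2
        np.testing.assert_allclose(psi, expected, rtol=1e-9)
        assert expected == pytest.approx(0.0399, abs=1e-4)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_quadratic_homogeneity(self, scale):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        np.testing.assert_allclose(
            teager_kaiser(scale * x), scale**2 * teager_kaiser(x), rtol=1e-9
        )

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            teager_kaiser(np.array([1.0, 2.0]))


class TestCountPulses:
    def test_zero_energy_zero_events(self):
        det = count_pulses(np.zeros(1000), 1.0, 0.01, 1000)
        assert det.count == 0

    def test_ten_pulses_recovered_at_injected_times(self):
        fs = 1000.0
        energy = np.zeros(11000)
        times = 1.0 + np.arange(10)
        for t in times:
            i = int(t * fs)
            energy[i - 2 : i + 3] = [3, 8, 10, 8, 3]
        det = count_pulses(energy, 1.0, 0.02, fs)
        assert det.count == 10
        np.testing.assert_allclose(det.event_times_s, times, atol=0.005)

    def test_threshold_above_peaks_gives_zero(self):
        energy = np.zeros(1000)
        energy[500] = 10.0
        assert count_pulses(energy, 11.0, 0.01, 1000).count == 0

    def test_nearby_excursions_merge(self):
        fs = 1000.0
        energy = np.zeros(1000)
        energy[100] = 5.0
        energy[105] = 5.0  # 5 ms apart, min_gap 20 ms -> one event
        assert count_pulses(energy, 1.0, 0.02, fs).count == 1
        assert count_pulses(energy, 1.0, 0.001, fs).count == 2

    def test_threshold_monotonicity_random_series(self, rng):
        for _ in range(50):
            energy = np.abs(rng.standard_normal(300)) ** 2
            thresholds = np.sort(rng.uniform(0.01, 4.0, 5))
            counts = [count_pulses(energy, t, 0.002, 1000).count for t in thresholds]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_agrees_with_brute_force_oracle(self, rng):
        fs = 1000.0
        for _ in range(200):
            energy = np.abs(rng.standard_normal(rng.integers(10, 300))) ** 2
            thr = float(rng.uniform(0.05, 3.0))
            gap_s = float(rng.uniform(0.001, 0.02))
            got = count_pulses(energy, thr, gap_s, fs).count
            want = brute_force_count(energy, thr, gap_s * fs)
            assert got == want


class TestDetectPipeline:
    def _pulse_segment(self, rng, n_pulses=15, fs=48000.0, dur=30.0):
        from reefscape.synth import fish_pulse

        x = 0.002 * rng.standard_normal(int(dur * fs))
        times = np.sort(rng.uniform(1.0, dur - 1.0, n_pulses))
        # enforce separation
        times = times[np.concatenate([[True], np.diff(times) > 0.4])]
        for t in times:
            w = fish_pulse(fs, 300.0, 0.08, 0.5)
            i = int(t * fs)
            x[i : i + len(w)] += w
        return CalibratedSegment(x, fs, T0, "s"), times

    def test_fish_pulses_recovered(self, rng):
        seg, times = self._pulse_segment(rng)
        det = detect(seg, fish_config(threshold=0.01))
        rep = validate(det.event_times_s, times, tolerance_s=0.01)
        assert rep.recall >= 0.95
        assert rep.precision >= 0.95

    def test_time_shift_equivariance(self, rng):
        fs = 48000.0
        from reefscape.synth import fish_pulse

        base = 0.002 * rng.standard_normal(int(4 * fs))
        w = fish_pulse(fs, 300.0, 0.08, 0.5)
        x1 = base.copy()
        x1[int(1.0 * fs) : int(1.0 * fs) + len(w)] += w
        x2 = base.copy()
        x2[int(2.5 * fs) : int(2.5 * fs) + len(w)] += w
        cfg = fish_config(threshold=0.01)
        t1 = detect(CalibratedSegment(x1, fs, T0, "s"), cfg).event_times_s
        t2 = detect(CalibratedSegment(x2, fs, T0, "s"), cfg).event_times_s
        assert len(t1) == len(t2) == 1
        assert t2[0] - t1[0] == pytest.approx(1.5, abs=0.002)

    def test_snaps_do_not_trigger_fish_detector(self, rng):
        from reefscape.synth import shrimp_snap

        fs = 48000.0
        x = 0.0005 * rng.standard_normal(int(10 * fs))
        for t in np.arange(0.5, 9.5, 0.5):
            w = shrimp_snap(fs, 1.0)
            i = int(t * fs)
            x[i : i + len(w)] += w
        seg = CalibratedSegment(x, fs, T0, "s")
        fish = detect(seg, fish_config(threshold=0.01))
        shrimp = detect(seg, shrimp_config(threshold=1e-3))
        assert shrimp.count == 18
        assert fish.count <= 1  # 4-9 kHz energy excluded by the 100-800 Hz band

    def test_band_above_sample_rate_errors(self, rng):
        seg = CalibratedSegment(rng.standard_normal(16000), 8000.0, T0, "s")
        with pytest.raises(ValueError, match="sample rate"):
            detect(seg, shrimp_config(threshold=1.0))

    def test_amplitude_scaling_scales_energy_quadratically(self, rng):
        from reefscape.detect import energy_trace

        seg, _ = self._pulse_segment(rng, n_pulses=5, dur=10.0)
        seg3 = CalibratedSegment(3 * seg.pressure_pa, seg.sample_rate_hz, T0, "s")
        e1, _ = energy_trace(seg, fish_config(1.0))
        e3, _ = energy_trace(seg3, fish_config(1.0))
        np.testing.assert_allclose(e3, 9 * e1, rtol=1e-7, atol=1e-12)


class TestValidate:
    def test_perfect_detection(self):
        truth = np.array([1.0, 2.0, 3.0])
        rep = validate(truth, truth, 0.01)
        assert rep.accuracy_pct == 100.0
        assert rep.precision == rep.recall == 1.0

    def test_empty_detections_zero_recall(self):
        rep = validate(np.array([]), np.array([1.0, 2.0]), 0.01)
        assert rep.recall == 0.0
        assert rep.false_negatives == 2

    def test_hand_worked_mixed_case(self):
        rep = validate(np.array([1.003, 5.0]), np.array([1.0, 2.0]), 0.01)
        assert (rep.true_positives, rep.false_positives, rep.false_negatives) == (1, 1, 1)
        assert rep.accuracy_pct == pytest.approx(33.3, abs=0.05)

    def test_each_truth_event_matched_once(self):
        # two detections near one truth event: only one may match
        rep = validate(np.array([0.999, 1.001]), np.array([1.0]), 0.01)
        assert rep.true_positives == 1
        assert rep.false_positives == 1
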