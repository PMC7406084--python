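import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from reefscape import spl
from reefscape.synth import (
    SceneConfig,
    diel_profile,
    draw_event_log,
    fish_pulse,
    render_scene,
    render_segment,
    shrimp_snap,
    snap_band,
)


def tiny_scene(**overrides) -> SceneConfig:
    base = dict(
        site_id="t", duration_h=2 / 60, sample_rate_hz=8000, seed=42,
        wind_series=(2.0,), tide_series=(1.0,),
        fish_rate_profile=(20.0,) * 24, shrimp_rate_profile=(60.0,) * 24,
    )
    base.update(overrides)
    return SceneConfig(**base)


class TestWaveforms:
    def test_fish_pulse_energy_inside_band(self):
        fs = 48000.0
        w = fish_pulse(fs, 400.0, 0.1, 1.0)
        f = np.fft.rfftfreq(len(w), 1 / fs)
        p = np.abs(np.fft.rfft(w)) ** 2
        in_band = p[(f >= 100) & (f <= 800)].sum()
        assert in_band / p.sum() > 0.95

    def test_fish_pulse_decays(self):
        w = fish_pulse(48000.0, 300.0, 0.1, 1.0)
        tail = w[int(0.75 * len(w)) :]
        assert np.max(np.abs(tail)) < 0.06  # beyond 3 damping constants

    def test_fish_pulse_amplitude_linearity(self):
        a = fish_pulse(48000.0, 300.0, 0.1, 1.0)
        b = fish_pulse(48000.0, 300.0, 0.1, 2.5)
        np.testing.assert_allclose(b, 2.5 * a, rtol=1e-12)

    def test_snap_shorter_than_100_ms(self):
        assert len(shrimp_snap(48000.0, 1.0)) / 48000.0 < 0.1

    def test_snap_band_energy_exceeds_fish_band(self):
        fs = 48000.0
        w = shrimp_snap(fs, 1.0)
        f = np.fft.rfftfreq(len(w), 1 / fs)
        p = np.abs(np.fft.rfft(w)) ** 2
        high = p[(f >= 4000) & (f <= 9000)].sum()
        low = p[(f >= 100) & (f <= 800)].sum()
        assert high > 10 * low

    def test_zero_amplitude_snap_is_silent(self):
        assert np.all(shrimp_snap(48000.0, 0.0) == 0)

    def test_snap_band_adapts_to_low_sample_rate(self):
        lo, hi = snap_band(8000.0)
        assert hi <= 0.9 * 4000.0
        assert lo >= 800.0
        assert snap_band(48000.0) == (4000.0, 9000.0)


class TestDielProfile:
    def test_peaks_at_requested_hours(self):
        prof = np.array(diel_profile((6, 18), base_rate=2, peak_rate=20))
        assert set(np.argsort(prof)[-2:]) == {6, 18}

    def test_flat_when_base_equals_peak(self):
        prof = diel_profile((6, 18), base_rate=5, peak_rate=5)
        np.testing.assert_allclose(prof, 5.0)

    def test_nonnegative(self):
        assert min(diel_profile((0, 12), 0.0, 30.0)) >= 0.0


class TestEventLog:
    def test_reproducible_given_seed(self):
        a = draw_event_log(tiny_scene())
        b = draw_event_log(tiny_scene())
        pd.testing.assert_frame_equal(a, b)

    def test_log_sorted_and_typed(self):
        log = draw_event_log(tiny_scene())
        assert log["time_s"].is_monotonic_increasing
        assert set(log["kind"]) <= {"fish", "shrimp"}

    def test_poisson_counts_match_rate(self):
        # chi-square GOF on per-scene fish counts across many seeds
        rate = 30.0  # events/min over 2 min -> lambda = 60
        counts = [
            (draw_event_log(tiny_scene(seed=s, fish_rate_profile=(rate,) * 24))
             .kind == "fish").sum()
            for s in range(120)
        ]
        lam = rate * 2
        assert np.mean(counts) == pytest.approx(lam, rel=0.05)
        assert np.var(counts) == pytest.approx(lam, rel=0.35)

    def test_min_separation_enforced(self):
        cfg = tiny_scene(shrimp_rate_profile=(600.0,) * 24, shrimp_min_sep_s=0.05)
        log = draw_event_log(cfg)
        snaps = log.loc[log["kind"] == "shrimp", "time_s"].to_numpy()
        assert np.all(np.diff(snaps) >= 0.05 - 1e-12)


class TestRenderScene:
    def test_silent_scene(self):
        cfg = tiny_scene(
            noise_floor_pa=0.0, wind_gain_pa=0.0, tide_gain_pa_per_m=0.0,
            fish_rate_profile=(0.0,) * 24, shrimp_rate_profile=(0.0,) * 24,
        )
        render = render_scene(cfg)
        assert render.events.empty
        assert np.all(render.segments()[0].pressure_pa == 0)

    def test_bit_identical_given_seed(self):
        a = render_segment(tiny_scene(), 0, draw_event_log(tiny_scene()))
        b = render_segment(tiny_scene(), 0, draw_event_log(tiny_scene()))
        np.testing.assert_array_equal(a.pressure_pa, b.pressure_pa)

    def test_log_count_equals_covariate_count(self):
        render = render_scene(tiny_scene())
        cov = render.covariates.iloc[0]
        assert cov["fish_count"] == (render.events.kind == "fish").sum()
        assert cov["shrimp_count"] == (render.events.kind == "shrimp").sum()

    def test_segments_are_exact_two_minutes(self):
        seg = render_scene(tiny_scene()).segments()[0]
        assert len(seg.pressure_pa) == 120 * 8000

    def test_wind_coupling_raises_low_band_leaves_2khz(self):
        quiet = tiny_scene(wind_series=(0.0,), fish_rate_profile=(0.0,) * 24,
                           shrimp_rate_profile=(0.0,) * 24)
        windy = tiny_scene(wind_series=(5.0,), fish_rate_profile=(0.0,) * 24,
                           shrimp_rate_profile=(0.0,) * 24)
        s_q = spl.spectrum(render_scene(quiet).segments()[0], centers_hz=(125.0, 2000.0))
        s_w = spl.spectrum(render_scene(windy).segments()[0], centers_hz=(125.0, 2000.0))
        assert s_w.band(125.0) - s_q.band(125.0) > 10.0
        assert abs(s_w.band(2000.0) - s_q.band(2000.0)) < 1.0

    def test_tide_component_sits_at_31p5_hz(self):
        cfg = tiny_scene(noise_floor_pa=0.0, wind_gain_pa=0.0,
                         tide_gain_pa_per_m=0.1,
                         fish_rate_profile=(0.0,) * 24, shrimp_rate_profile=(0.0,) * 24)
        spec = spl.spectrum(render_scene(cfg).segments()[0],
                            centers_hz=(31.5, 125.0, 500.0))
        assert spec.band(31.5) > spec.band(125.0) + 20
        assert spec.band(31.5) > spec.band(500.0) + 20

    def test_beaufort_bounds_enforced(self):
        with pytest.raises(ValueError, match="Beaufort"):
            tiny_scene(wind_series=(13.0,))
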