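import numpy as np
import pandas as pd
import pytest

import cardiotfa as ct
from cardiotfa.errors import ValidationError
from cardiotfa.tfa import WelchConfig, _band_for_frequency


def make_series(values, rate=4.0, **kw):
    return ct.UniformSeries(np.asarray(values, dtype=float), rate=rate, **kw)


def beat_frame(times, values):
    return pd.DataFrame({"beat_onset_time": times, "mean": values})


class TestSplineResample:
    def test_linear_ramp_reproduced(self):
        t = np.linspace(0, 100, 120)
        bt = beat_frame(t, 2.0 * t + 5.0)
        out = ct.spline_resample(bt, "mean", rate=4.0)
        expect = 2.0 * (t[0] + np.arange(out.values.size) / 4.0) + 5.0
        np.testing.assert_allclose(out.values, expect, rtol=1e-6)

    def test_sinusoid_amplitude_preserved(self):
        # beat-mean series at ~90 beats/min carrying a 0.05 Hz oscillation
        rng = np.random.default_rng(3)
        t = np.cumsum(rng.normal(60 / 90, 0.01, 400))
        t = t[t < 240]
        bt = beat_frame(t, 90 + 10 * np.sin(2 * np.pi * 0.05 * t))
        out = ct.spline_resample(bt, "mean", rate=4.0)
        grid = t[0] + np.arange(out.values.size) / 4.0
        w = 2 * np.pi * 0.05 * grid
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones_like(grid), np.sin(w), np.cos(w)]),
            out.values, rcond=None,
        )
        assert np.hypot(coef[1], coef[2]) == pytest.approx(10.0, rel=0.01)

    def test_240s_at_4hz_gives_960_samples(self):
        t = np.linspace(0, 239.9, 300)
        out = ct.spline_resample(bt := beat_frame(t, np.ones(300)), "mean",
                                 rate=4.0, t_start=0.0, duration=240.0)
        assert out.values.size == 960

    def test_duplicate_beat_times_rejected(self):
        t = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        with pytest.raises(ValidationError):
            ct.spline_resample(beat_frame(t, np.arange(8.0)), "mean")

    def test_too_few_beats_rejected(self):
        t = np.arange(5.0)
        with pytest.raises(ValidationError):
            ct.spline_resample(beat_frame(t, t), "mean")


class TestSegmentWindows:
    @pytest.mark.parametrize(
        "duration,expected", [(240.0, 5), (80.0, 1), (200.0, 4)]
    )
    def test_window_count_formula(self, duration, expected):
        series = make_series(np.zeros(int(duration * 4)))
        assert len(ct.segment_windows(series, WelchConfig())) == expected

    def test_window_longer_than_record_rejected(self):
        series = make_series(np.zeros(100))
        with pytest.raises(ValidationError):
            ct.segment_windows(series, WelchConfig(window_length=80.0))

    def test_windows_are_detrended_and_tapered(self):
        series = make_series(np.arange(960.0))
        windows = ct.segment_windows(series, WelchConfig())
        for w in windows:
            # a linear ramp detrends to ~zero before tapering
            assert np.abs(w).max() < 1e-8


class TestWelchSpectra:
    @pytest.fixture(scope="class")
    def x(self):
        rng = np.random.default_rng(17)
        return make_series(rng.standard_normal(960))

    def test_identity_pair(self, x):
        s = ct.welch_spectra(x, x)
        np.testing.assert_allclose(s.coherence, 1.0, atol=1e-9)
        np.testing.assert_allclose(s.gain[1:], 1.0, atol=1e-9)
        np.testing.assert_allclose(s.phase, 0.0, atol=1e-9)

    def test_doubling_gain(self, x):
        y = make_series(2.0 * x.values)
        s = ct.welch_spectra(x, y)
        mask = s.psd_input > 0
        np.testing.assert_allclose(s.gain[mask], 2.0, atol=1e-9)
        np.testing.assert_allclose(s.coherence[mask], 1.0, atol=1e-9)

    def test_coherence_bounded_for_unrelated_signals(self, x):
        rng = np.random.default_rng(99)
        y = make_series(rng.standard_normal(960))
        s = ct.welch_spectra(x, y)
        assert np.all(s.coherence >= 0.0)
        assert np.all(s.coherence <= 1.0)

    def test_parseval_white_noise(self):
        # 100 windows: integral of the PSD matches the mean per-window
        # variance of the detrended, taper-corrected input within 1%
        cfg = WelchConfig()
        rng = np.random.default_rng(0)
        n = 99 * 160 + 320
        x = make_series(rng.standard_normal(n))
        s = ct.welch_spectra(x, x, cfg)
        assert s.n_windows == 100
        integral = np.trapezoid(s.psd_input, s.freqs)
        variances = []
        for k in range(100):
            seg = x.values[k * 160 : k * 160 + 320]
            seg = seg - np.polyval(np.polyfit(np.arange(320), seg, 1), np.arange(320))
            variances.append(seg.var())
        assert integral == pytest.approx(np.mean(variances), rel=0.01)

    def test_noise_in_output_decreases_coherence(self):
        rng = np.random.default_rng(5)
        t = np.arange(960) / 4.0
        x = make_series(np.sin(2 * np.pi * 0.05 * t))
        bin_idx = 4
        last = 1.1
        for sd in (0.1, 0.5, 1.0):
            y = make_series(x.values + rng.normal(0, sd, x.values.size))
            c = ct.welch_spectra(x, y).coherence[bin_idx]
            assert c < last
            last = c

    def test_pure_delay_phase_convention(self):
        # y(t) = x(t - tau) must give phase -2*pi*f*tau at the tone bin;
        # exact without detrending, slightly perturbed by per-window lines
        t = np.arange(960) / 4.0
        tau = 2.5
        f0 = 0.05
        x = make_series(np.sin(2 * np.pi * f0 * t))
        y = make_series(np.sin(2 * np.pi * f0 * (t - tau)))
        expected = -2 * np.pi * f0 * tau
        s = ct.welch_spectra(x, y, WelchConfig(detrend="none"))
        idx = int(np.argmin(np.abs(s.freqs - f0)))
        assert s.phase[idx] == pytest.approx(expected, abs=1e-9)
        s_lin = ct.welch_spectra(x, y)
        assert s_lin.phase[idx] == pytest.approx(expected, abs=0.01)

    def test_single_window_rejected(self):
        x = make_series(np.zeros(320))
        with pytest.raises(ValidationError):
            ct.welch_spectra(x, x, WelchConfig(overlap_fraction=0.0))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            ct.welch_spectra(make_series(np.zeros(960)), make_series(np.zeros(640)))


class TestPointMetrics:
    @pytest.fixture(scope="class")
    def tone_pair(self):
        # noiseless y = baseline-free G-scaled oscillation advanced by 0.40 rad
        t = np.arange(960) / 4.0
        f0, g, phi = 0.05, 0.8, 0.40
        x = make_series(10 * np.sin(2 * np.pi * f0 * t))
        y = make_series(g * 10 * np.sin(2 * np.pi * f0 * t + phi))
        return ct.welch_spectra(x, y)

    def test_known_transfer_recovered(self, tone_pair):
        pm = ct.point_metrics(tone_pair, 0.05, mean_output_level=50.0)
        assert pm.gain == pytest.approx(0.8, rel=0.02)
        assert pm.phase == pytest.approx(0.40, abs=0.02)
        assert pm.coherence >= 0.99
        assert pm.coherence_pass

    def test_ngain_definition(self, tone_pair):
        pm = ct.point_metrics(tone_pair, 0.05, mean_output_level=50.0)
        assert pm.ngain == pytest.approx(pm.gain / 50.0 * 100.0, rel=1e-12)

    def test_coherence_boundary_fails_criterion(self, tone_pair):
        s = tone_pair
        s.coherence = np.full_like(s.coherence, 0.45)
        pm = ct.point_metrics(s, 0.05, mean_output_level=50.0, critical_coherence=0.46)
        assert not pm.coherence_pass

    def test_frequency_above_nyquist_rejected(self, tone_pair):
        with pytest.raises(ValidationError):
            ct.point_metrics(tone_pair, 3.0, mean_output_level=50.0)

    def test_ngain_matches_prenormalized_series_gain(self):
        # computing gain on an output pre-normalized to %-of-mean equals
        # ngain computed post hoc from the raw-output gain
        rng = np.random.default_rng(11)
        t = np.arange(960) / 4.0
        x = make_series(90 + 10 * np.sin(2 * np.pi * 0.05 * t))
        yv = 60 + 8 * np.sin(2 * np.pi * 0.05 * t + 0.3) + rng.normal(0, 0.5, t.size)
        y = make_series(yv)
        mean_level = yv.mean()
        pm = ct.point_metrics(ct.welch_spectra(x, y), 0.05, mean_output_level=mean_level)
        y_norm = make_series(yv / mean_level * 100.0)
        pm_norm = ct.point_metrics(ct.welch_spectra(x, y_norm), 0.05, mean_output_level=100.0)
        assert pm.ngain == pytest.approx(pm_norm.gain, rel=1e-6)


class TestDetectWraparound:
    def test_smooth_ramp_is_clean(self):
        freqs = np.arange(0, 0.5, 0.0125)
        phase = np.linspace(0, 0.5, freqs.size)
        assert not ct.detect_wraparound(freqs, phase, (0.02, 0.20))

    def test_jump_is_flagged(self):
        freqs = np.arange(0, 0.5, 0.0125)
        phase = np.linspace(0, 0.5, freqs.size)
        phase[10:] += 2 * np.pi
        assert ct.detect_wraparound(freqs, phase, (0.02, 0.20))

    def test_single_bin_band_is_vacuous(self):
        freqs = np.arange(0, 0.5, 0.0125)
        phase = np.zeros(freqs.size)
        assert not ct.detect_wraparound(freqs, phase, (0.049, 0.051))

    def test_empty_band_rejected(self):
        with pytest.raises(ValidationError):
            ct.detect_wraparound(np.array([0.05, 0.10]), np.zeros(2), (0.06, 0.07))

    def test_band_selection_tracks_autoregulation_ranges(self):
        assert _band_for_frequency(0.05, 0.0125) == (0.02, 0.07)
        assert _band_for_frequency(0.10, 0.0125) == (0.07, 0.20)
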