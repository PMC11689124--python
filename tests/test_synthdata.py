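import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram

import cardiotfa as ct
from cardiotfa.errors import ValidationError
from cardiotfa.synthdata import _fit_sinusoid


def sinusoid_amplitude(t, x, freq):
    """Independent least-squares sinusoid regression oracle."""
    w = 2 * np.pi * freq * t
    design = np.column_stack([np.ones_like(t), np.sin(w), np.cos(w)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(np.hypot(coef[1], coef[2]))


class TestSimulateBpWaveform:
    def test_unforced_beat_count_and_levels(self, clean_bp_60bpm):
        rec = clean_bp_60bpm
        onsets = ct.detect_beats(rec.bp, rec.sample_rate)
        bt = ct.decompose_beats(rec.bp, onsets, rec.sample_rate)
        assert abs(len(bt) - 60) <= 1
        assert np.allclose(bt["systolic"], 120.0, rtol=0.01)
        assert np.allclose(bt["diastolic"], 80.0, rtol=0.01)

    def test_forcing_amplitude_recovered_from_beat_means(self):
        rec = ct.simulate_bp_waveform(
            hr=90, forcing_freq=0.05, forcing_amp=10.0, duration=240, seed=3
        )
        onsets = ct.detect_beats(rec.bp, rec.sample_rate)
        bt = ct.decompose_beats(rec.bp, onsets, rec.sample_rate)
        amp = sinusoid_amplitude(
            bt["beat_onset_time"].to_numpy(), bt["mean"].to_numpy(), 0.05
        )
        assert amp == pytest.approx(10.0, rel=0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(hr=25),
            dict(hr=250),
            dict(dbp=130.0),
            dict(duration=-1.0),
            dict(sample_rate=-10.0),
            dict(hr=30, forcing_freq=0.3),  # cardiac rate below 2x forcing
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        base = dict(hr=75, duration=30, seed=0)
        with pytest.raises(ValidationError):
            ct.simulate_bp_waveform(**{**base, **kwargs})

    @pytest.mark.parametrize("freq", [0.05, 0.10])
    def test_forcing_energy_lands_at_the_forcing_bin(self, freq):
        rec = ct.simulate_bp_waveform(
            hr=90, forcing_freq=freq, forcing_amp=10.0, duration=240, seed=9
        )
        onsets = ct.detect_beats(rec.bp, rec.sample_rate)
        bt = ct.decompose_beats(rec.bp, onsets, rec.sample_rate)
        series = ct.spline_resample(bt, "mean", rate=4.0)
        f, pxx = periodogram(series.values - series.values.mean(), fs=4.0)
        assert f[np.argmax(pxx)] == pytest.approx(freq, abs=f[1] / 2)


class TestApplyTransfer:
    def test_zero_gain_gives_flat_velocity_beats(self, forced_recording):
        truths = [
            ct.TransferTruth("MCA", c, 0.0, 0.0, base)
            for c, base in (("diastolic", 45.0), ("mean", 60.0), ("systolic", 95.0))
        ]
        rec, _ = ct.apply_transfer(forced_recording, truths, noise_sd=0.0, seed=0)
        onsets = ct.detect_beats(rec.bp, rec.sample_rate)
        bt = ct.decompose_beats(rec.mcav, onsets, rec.sample_rate)
        # flat up to sub-cm/s discretization noise of the window average
        assert bt["mean"].std() < 0.2
        assert np.allclose(bt["mean"], 60.0, atol=0.5)

    def test_unit_gain_zero_phase_tracks_bp_means(self, forced_recording):
        truths = [
            ct.TransferTruth("MCA", c, 1.0, 0.0, base)
            for c, base in (("diastolic", 45.0), ("mean", 65.0), ("systolic", 95.0))
        ]
        rec, _ = ct.apply_transfer(forced_recording, truths, noise_sd=0.0, seed=0)
        onsets = ct.detect_beats(rec.bp, rec.sample_rate)
        bp_bt = ct.decompose_beats(rec.bp, onsets, rec.sample_rate)
        v_bt = ct.decompose_beats(rec.mcav, onsets, rec.sample_rate)
        r = np.corrcoef(bp_bt["mean"], v_bt["mean"])[0, 1]
        assert r >= 0.999

    def test_positive_phase_means_velocity_leads(self, forced_recording):
        # phase +0.40 rad at 0.05 Hz <=> velocity peak 0.40/(2*pi*0.05) = 1.273 s early
        truths = [
            ct.TransferTruth("MCA", c, 1.0, 0.40, base)
            for c, base in (("diastolic", 45.0), ("mean", 65.0), ("systolic", 95.0))
        ]
        rec, _ = ct.apply_transfer(forced_recording, truths, noise_sd=0.0, seed=0)
        onsets = ct.detect_beats(rec.bp, rec.sample_rate)
        bp_bt = ct.decompose_beats(rec.bp, onsets, rec.sample_rate)
        v_bt = ct.decompose_beats(rec.mcav, onsets, rec.sample_rate)
        # cross-correlation oracle on spline-gridded beat-mean series
        x = ct.spline_resample(bp_bt, "mean", rate=4.0).values
        y = ct.spline_resample(v_bt, "mean", rate=4.0).values
        x = x - x.mean()
        y = y - y.mean()
        lags = np.arange(-40, 41)  # +-10 s at 4 Hz
        cc = [np.dot(np.roll(y, k), x) for k in lags]
        lag = lags[int(np.argmax(cc))] / 4.0
        assert lag == pytest.approx(0.40 / (2 * np.pi * 0.05), abs=0.3)

    def test_negative_gain_rejected(self, forced_recording):
        with pytest.raises(ValidationError):
            ct.TransferTruth("MCA", "mean", -0.5, 0.0, 60.0)

    def test_missing_bp_rejected(self):
        rec = ct.RawRecording(
            time=np.arange(100) / 10.0, bp=np.ones(100), sample_rate=10.0
        )
        rec.bp = None
        with pytest.raises((ValidationError, AttributeError, TypeError)):
            ct.apply_transfer(rec, ct.default_transfer_truths("eucapnia", 0.05))

    def test_partial_component_set_rejected(self, forced_recording):
        with pytest.raises(ValidationError):
            ct.apply_transfer(
                forced_recording,
                [ct.TransferTruth("MCA", "mean", 1.0, 0.0, 60.0)],
            )


class TestSimulatePetco2:
    def test_clamped_peaks_at_target(self):
        trace = ct.simulate_petco2(40.0, breath_rate=15, duration=120, jitter_sd=0.0, seed=0)
        peaks = ct.extract_breath_peaks(trace, 250.0)
        assert np.all(np.abs(peaks["petco2_peak"] - 40.0) <= 1.0)

    def test_breath_count_matches_rate(self):
        trace = ct.simulate_petco2(40.0, breath_rate=20, duration=60, jitter_sd=0.0, seed=1)
        peaks = ct.extract_breath_peaks(trace, 250.0)
        assert abs(len(peaks) - 20) <= 1

    def test_stage_separation(self):
        lo = ct.simulate_petco2(25.0, duration=120, jitter_sd=0.0, seed=2)
        hi = ct.simulate_petco2(55.0, duration=120, jitter_sd=0.0, seed=2)
        m_lo = ct.extract_breath_peaks(lo, 250.0).attrs["mean_peak"]
        m_hi = ct.extract_breath_peaks(hi, 250.0).attrs["mean_peak"]
        assert m_hi - m_lo == pytest.approx(30.0, abs=0.5)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValidationError):
            ct.simulate_petco2(-5.0)


class TestGenerateCohort:
    @pytest.fixture(scope="class")
    def small_spec(self):
        return ct.CohortSpec(
            n_female=1, n_male=1, ssm_frequencies=(0.05, 0.10), duration=120,
            sample_rate=100.0, seed=42,
        )

    def test_one_recording_per_cell(self, small_spec):
        recs, truth = ct.generate_cohort(small_spec)
        assert len(recs) == 2 * 3 * 2
        # every transfer used appears in the truth table
        assert len(truth) == len(recs) * 6

    def test_determinism_under_fixed_seed(self, small_spec):
        a, truth_a = ct.generate_cohort(small_spec)
        b, truth_b = ct.generate_cohort(small_spec)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.bp, rb.bp)
            np.testing.assert_array_equal(ra.mcav, rb.mcav)
            np.testing.assert_array_equal(ra.petco2, rb.petco2)
        pd.testing.assert_frame_equal(truth_a, truth_b)

    def test_default_phase_ordering_follows_co2_stages(self):
        # mean MCA phase: hypocapnia > eucapnia > hypercapnia
        phases = {
            stage: next(
                t.phase_true
                for t in ct.default_transfer_truths(stage, 0.05)
                if t.vessel == "MCA" and t.component == "mean"
            )
            for stage in ("hypocapnia", "eucapnia", "hypercapnia")
        }
        assert phases["hypocapnia"] > phases["eucapnia"] > phases["hypercapnia"]

    def test_baseline_velocity_rises_with_co2(self):
        bases = {
            stage: next(
                t.baseline_velocity
                for t in ct.default_transfer_truths(stage, 0.05)
                if t.vessel == "MCA" and t.component == "mean"
            )
            for stage in ("hypocapnia", "eucapnia", "hypercapnia")
        }
        assert bases["hypercapnia"] > bases["eucapnia"] > bases["hypocapnia"]

    def test_empty_stages_rejected(self):
        with pytest.raises(ValidationError):
            ct.CohortSpec(stages=())


class TestTransitionsPerMinute:
    @pytest.mark.parametrize("freq,expected", [(0.05, 6.0), (0.10, 12.0)])
    def test_metronome_pacing(self, freq, expected):
        assert ct.transitions_per_minute(freq) == pytest.approx(expected)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValidationError):
            ct.transitions_per_minute(0.0)


def test_fit_sinusoid_recovers_known_parameters():
    t = np.linspace(0, 200, 331)
    x = 5.0 + 3.0 * np.sin(2 * np.pi * 0.05 * t + 1.1)
    amp, phi = _fit_sinusoid(t, x, 0.05)
    assert amp == pytest.approx(3.0, rel=1e-9)
    assert phi == pytest.approx(1.1, abs=1e-9)
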