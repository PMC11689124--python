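"""Synthetic squat-stand cohort generator with known transfer ground truth.

The simulator emulates the signals of a CO2-clamped squat-stand protocol:
pulsatile arterial blood pressure (BP) whose per-beat systolic and diastolic
levels carry a forced sinusoidal oscillation at the manoeuvre pacing frequency
(0.05 or 0.10 Hz), middle/posterior cerebral artery velocity (MCAv/PCAv)
channels obtained by applying a known linear transfer (gain, phase) to each
cardiac-cycle component of the BP oscillation, and a breath-wise end-tidal CO2
(PETCO2) trace clamped near the stage target.

Every recording is produced from an explicit seed and the injected transfer
parameters are returned alongside, so the downstream beat-decomposition and
transfer-function stages can be tested by parameter recovery instead of
against undeposited participant data.

The pulse kernel is deliberately minimal: a half-raised-cosine upstroke from
the diastolic foot to the systolic peak over a ``systolic_fraction`` of the
beat, followed by an exponential run-off that terminates on a small ledge
just above the larger of the beat's own foot and the next beat's foot.  The
ledge guarantees that the minimum between two systolic peaks is always the
intervening foot: without it, whenever diastolic levels change quickly from
one beat to the next, the window minimum reads the neighbouring beat's level
instead, attenuating and phase-advancing the extracted diastolic series.  Its
per-beat maximum, minimum and time-average are therefore unambiguous, and the
beat mean has a closed form used both to invert the kernel (so velocity beats
hit an exact mean target) and as an independent oracle in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "PulseShapeParams",
    "TransferTruth",
    "CohortSpec",
    "RawRecording",
    "simulate_bp_waveform",
    "apply_transfer",
    "simulate_petco2",
    "generate_cohort",
    "transitions_per_minute",
    "default_transfer_truths",
    "STAGES",
    "VESSELS",
    "COMPONENTS",
]

STAGES = ("hypocapnia", "eucapnia", "hypercapnia")
VESSELS = ("MCA", "PCA")
COMPONENTS = ("diastolic", "mean", "systolic")

#: R-R interval jitter: Gaussian sd as a fraction of the mean interval,
#: truncated at +-10% (realistic beat-time irregularity without aliasing).
RR_JITTER_FRAC = 0.02
RR_JITTER_TRUNC = 0.10


@dataclass(frozen=True)
class PulseShapeParams:
    """Shape of one pressure/velocity pulse.

    systolic_fraction
        Fraction of the beat occupied by the upstroke-to-peak segment, in (0, 1).
    decay_rate
        Diastolic run-off constant in 1/s; larger values return the waveform
        to the diastolic level faster after the systolic peak.
    end_diastolic_offset
        Margin, as a fraction of pulse height, by which the end-diastolic
        ledge sits above the larger of the beat's own foot and the next
        beat's foot.  Keeps every inter-beat minimum at the intervening foot
        regardless of how fast the diastolic level is changing.
    """

    systolic_fraction: float = 0.30
    decay_rate: float = 7.0
    end_diastolic_offset: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValidationError("systolic_fraction must lie in (0, 1)")
        if self.decay_rate <= 0:
            raise ValidationError("decay_rate must be positive")
        if not 0.0 <= self.end_diastolic_offset < 0.5:
            raise ValidationError("end_diastolic_offset must lie in [0, 0.5)")


@dataclass(frozen=True)
class TransferTruth:
    """Injected linear BP->CBv transfer for one cardiac-cycle component.

    Sign convention: positive ``phase_true`` means the velocity oscillation
    leads the pressure oscillation (the physiological reading of an active
    autoregulatory phase lead).
    """

    vessel: str
    component: str
    gain_true: float  # cm/s per mmHg
    phase_true: float  # radians, in (-pi, pi]
    baseline_velocity: float  # cm/s

    def __post_init__(self) -> None:
        if self.vessel not in VESSELS:
            raise ValidationError(f"unknown vessel {self.vessel!r}")
        if self.component not in COMPONENTS:
            raise ValidationError(f"unknown component {self.component!r}")
        if self.gain_true < 0:
            raise ValidationError("gain_true must be >= 0")
        if not -np.pi < self.phase_true <= np.pi:
            raise ValidationError("phase_true must lie in (-pi, pi]")
        if self.baseline_velocity <= 0:
            raise ValidationError("baseline_velocity must be positive")


@dataclass
class RawRecording:
    """Uniformly sampled multichannel squat-stand recording."""

    time: np.ndarray  # s
    bp: np.ndarray  # mmHg
    sample_rate: float  # Hz
    mcav: np.ndarray | None = None  # cm/s
    pcav: np.ndarray | None = None  # cm/s
    petco2: np.ndarray | None = None  # mmHg
    participant: str = "P01"
    sex: str = "female"
    stage: str = "eucapnia"
    ssm_frequency: float | None = None  # Hz
    seed: int | None = None
    # Simulator ground truth (beat onsets and per-beat BP levels); not written
    # to disk, used by apply_transfer and by recovery tests.
    truth_beats: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.bp = np.asarray(self.bp, dtype=float)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        n = self.time.size
        for name in ("bp", "mcav", "pcav", "petco2"):
            ch = getattr(self, name)
            if ch is not None and np.asarray(ch).size != n:
                raise ValidationError(f"channel {name} length differs from time")
        dt = np.diff(self.time)
        if n > 1 and (dt.min() <= 0 or np.ptp(dt) > 1e-6):
            raise ValidationError("time must increase with a constant step")
        if np.any(self.bp <= 0):
            raise ValidationError("bp must be positive throughout")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.time.size / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        out = getattr(self, name)
        if out is None:
            raise ValidationError(f"recording has no {name!r} channel")
        return out


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the emulated protocol: 10 females + 10 males, three CO2
    stages clamped at 25/40/55 mmHg, squat-stand pacing at 0.05 and 0.10 Hz,
    4-min recordings.
    """

    n_female: int = 10
    n_male: int = 10
    stages: Sequence[str] = STAGES
    ssm_frequencies: Sequence[float] = (0.05, 0.10)
    duration: float = 240.0  # s
    sample_rate: float = 250.0  # Hz
    petco2_targets: dict[str, float] | None = None  # mmHg per stage
    forcing_amplitude: float = 10.0  # mmHg
    noise_sd: float = 1.0  # cm/s, per-beat velocity measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if self.sample_rate < 20:
            raise ValidationError("sample_rate must be >= 20 Hz")
        if self.forcing_amplitude < 0:
            raise ValidationError("forcing_amplitude must be >= 0")
        if not self.stages:
            raise ValidationError("stages must be non-empty")
        if not self.ssm_frequencies:
            raise ValidationError("ssm_frequencies must be non-empty")
        for s in self.stages:
            if s not in STAGES:
                raise ValidationError(f"unknown stage {s!r}")
        tg = self.targets
        if any(v <= 0 for v in tg.values()):
            raise ValidationError("petco2_targets must be positive")

    @property
    def targets(self) -> dict[str, float]:
        if self.petco2_targets is not None:
            return dict(self.petco2_targets)
        return {"hypocapnia": 25.0, "eucapnia": 40.0, "hypercapnia": 55.0}


# ---------------------------------------------------------------------------
# Pulse kernel
# ---------------------------------------------------------------------------

def _ledge_fractions(
    dia_levels: np.ndarray, sys_levels: np.ndarray, margin: float
) -> np.ndarray:
    """End-diastolic ledge level per beat, as a fraction of pulse height.

    The run-off of beat i terminates at ``margin`` of the pulse height above
    ``max(dia_i, dia_{i+1})`` (own foot for the final beat), clipped below
    0.45 so a pathological foot sequence cannot push the ledge into systole.
    """
    dia_next = np.concatenate([dia_levels[1:], dia_levels[-1:]])
    rise = np.maximum(0.0, dia_next - dia_levels)
    e = rise / (sys_levels - dia_levels) + margin
    return np.clip(e, margin, 0.45)


def _beat_mean_fraction(
    sf: np.ndarray | float,
    lam_rr: np.ndarray | float,
    edo: np.ndarray | float = 0.02,
):
    """Closed-form beat mean of the kernel as a fraction of (sys - dia).

    The upstroke contributes sf/2; the run-off, normalized to fall from 1 at
    the peak to the ledge fraction ``edo`` at the beat end, contributes
    (1-sf) * (edo + (1-edo) * gbar) with gbar the mean of the residual-free
    exponential shape, gbar = (1 - e^-z)/z - e^-z/2, z = lam*rr*(1-sf).
    Monotone increasing in sf on (0, 1).
    """
    sf = np.asarray(sf, dtype=float)
    lam_rr = np.asarray(lam_rr, dtype=float)
    edo = np.asarray(edo, dtype=float)
    z = lam_rr * (1.0 - sf)
    gbar = (1.0 - np.exp(-z)) / z - np.exp(-z) / 2.0
    return sf / 2.0 + (1.0 - sf) * (edo + (1.0 - edo) * gbar)


def _invert_mean_fraction(
    m_req: np.ndarray, lam_rr: np.ndarray, edo: np.ndarray | float = 0.02
) -> np.ndarray:
    """Solve systolic fraction sf so the kernel's beat-mean fraction equals m_req.

    m_req is clipped into the achievable open interval before a vectorized
    bisection (48 iterations, well below float precision on sf).
    """
    lam_rr = np.asarray(lam_rr, dtype=float)
    lo = np.full_like(lam_rr, 1e-3)
    hi = np.full_like(lam_rr, 1.0 - 1e-3)
    m_lo = _beat_mean_fraction(lo, lam_rr, edo)
    m_hi = _beat_mean_fraction(hi, lam_rr, edo)
    m = np.clip(m_req, m_lo + 1e-9, m_hi - 1e-9)
    clipped = np.abs(m - m_req) > 1e-6
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} beat-mean targets fell outside the pulse "
            "kernel's achievable range and were clipped",
            RuntimeWarning,
            stacklevel=2,
        )
    a, b = lo.copy(), hi.copy()
    for _ in range(48):
        mid = 0.5 * (a + b)
        too_low = _beat_mean_fraction(mid, lam_rr, edo) < m
        a = np.where(too_low, mid, a)
        b = np.where(too_low, b, mid)
    return 0.5 * (a + b)


def _pulse_train(
    t: np.ndarray,
    onsets: np.ndarray,
    dia_levels: np.ndarray,
    sys_levels: np.ndarray,
    sf: np.ndarray,
    decay_rate: float,
    edo: np.ndarray,
) -> np.ndarray:
    """Sample the piecewise pulse kernel over a beat grid.

    ``onsets`` has one more entry than there are beats; sample i belongs to the
    half-open beat [onset_k, onset_{k+1}) found by search.  The run-off falls
    from the peak to the per-beat ledge ``dia + edo * (sys - dia)``.
    """
    rr = np.diff(onsets)
    k = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, rr.size - 1)
    u = (t - onsets[k]) / rr[k]
    dia, sys_, sfk, ek = dia_levels[k], sys_levels[k], sf[k], edo[k]
    amp = sys_ - dia
    out = np.empty_like(t)
    up = u <= sfk
    out[up] = dia[up] + amp[up] * 0.5 * (1.0 - np.cos(np.pi * u[up] / sfk[up]))
    dn = ~up
    # Exponential shape normalized to fall from 1 at the peak to 0 at the
    # beat end (a linear ramp absorbs the end-of-beat residual), then lifted
    # onto the end-diastolic ledge.
    frac = (u[dn] - sfk[dn]) / (1.0 - sfk[dn])
    resid = np.exp(-decay_rate * rr[k][dn] * (1.0 - sfk[dn]))
    shape = np.exp(-decay_rate * rr[k][dn] * (u[dn] - sfk[dn])) - resid * frac
    out[dn] = dia[dn] + amp[dn] * (ek[dn] + (1.0 - ek[dn]) * shape)
    return out


def _beat_onsets(hr: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    """Beat onset times with truncated-Gaussian R-R jitter.

    Every returned onset except the last lies inside the record; the final
    onset falls at or beyond ``duration`` and only closes the last beat.
    """
    mean_rr = 60.0 / hr
    n_max = int(np.ceil(duration / (mean_rr * (1.0 - RR_JITTER_TRUNC)))) + 4
    jit = np.clip(
        rng.normal(0.0, RR_JITTER_FRAC, size=n_max), -RR_JITTER_TRUNC, RR_JITTER_TRUNC
    )
    rr = mean_rr * (1.0 + jit)
    onsets = np.concatenate([[0.0], np.cumsum(rr)])
    last = int(np.searchsorted(onsets, duration))
    return onsets[: last + 1]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def simulate_bp_waveform(
    hr: float,
    sbp: float = 120.0,
    dbp: float = 80.0,
    forcing_freq: float = 0.05,
    forcing_amp: float = 10.0,
    duration: float = 240.0,
    sample_rate: float = 250.0,
    pulse: PulseShapeParams | None = None,
    seed: int | np.random.Generator = 0,
) -> RawRecording:
    """Simulate a pulsatile BP trace with a forced sinusoidal oscillation.

    Per-beat diastolic and systolic levels each carry an additive sinusoid
    ``forcing_amp * sin(2*pi*forcing_freq*t)`` evaluated at the beat onset, so
    every cardiac-cycle component of the beat series oscillates with the same
    amplitude and phase -- which makes downstream transfer truths exactly
    linear in the injected oscillation.
    """
    pulse = pulse or PulseShapeParams()
    if duration <= 0 or sample_rate <= 0:
        raise ValidationError("duration and sample_rate must be positive")
    if not 30.0 <= hr <= 220.0:
        raise ValidationError("hr must lie in [30, 220] beats/min")
    if dbp >= sbp:
        raise ValidationError("dbp must be below sbp")
    if forcing_freq < 0 or forcing_amp < 0:
        raise ValidationError("forcing_freq and forcing_amp must be >= 0")
    if forcing_freq > 0 and hr / 60.0 <= 2.0 * forcing_freq:
        raise ValidationError("cardiac frequency must exceed twice the forcing frequency")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    onsets = _beat_onsets(hr, duration, rng)
    t_beat = onsets[:-1]
    osc = forcing_amp * np.sin(2.0 * np.pi * forcing_freq * t_beat)
    dia = dbp + osc
    sys_ = sbp + osc

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    sf = np.full(t_beat.size, pulse.systolic_fraction)
    ledge = _ledge_fractions(dia, sys_, pulse.end_diastolic_offset)
    bp = _pulse_train(t, onsets, dia, sys_, sf, pulse.decay_rate, ledge)

    rr = np.diff(onsets)
    mean_frac = _beat_mean_fraction(sf, pulse.decay_rate * rr, ledge)
    truth = pd.DataFrame(
        {
            "onset_time": t_beat,
            "rr_interval": rr,
            "bp_diastolic": dia,
            "bp_systolic": sys_,
            "bp_mean": dia + (sys_ - dia) * mean_frac,
            "forcing_osc": osc,
        }
    )
    return RawRecording(
        time=t,
        bp=bp,
        sample_rate=sample_rate,
        ssm_frequency=forcing_freq if forcing_amp > 0 else None,
        truth_beats=truth,
    )


def _fit_sinusoid(t: np.ndarray, x: np.ndarray, freq: float) -> tuple[float, float]:
    """Least-squares fit of ``a + R*sin(2*pi*freq*t + phi)``; returns (R, phi)."""
    w = 2.0 * np.pi * freq * t
    design = np.column_stack([np.ones_like(t), np.sin(w), np.cos(w)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    b, c = coef[1], coef[2]
    return float(np.hypot(b, c)), float(np.arctan2(c, b))


def apply_transfer(
    bp_recording: RawRecording,
    truths: Iterable[TransferTruth],
    forcing_freq: float | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    pulse: PulseShapeParams | None = None,
) -> tuple[RawRecording, pd.DataFrame]:
    """Add velocity channels realizing known component-specific transfers.

    For each vessel with truths, the per-beat diastolic/mean/systolic velocity
    targets are ``baseline + gain * osc_c(t + phase/(2*pi*f))`` plus optional
    Gaussian noise, where ``osc_c`` is the sinusoid fitted at the forcing
    frequency to the corresponding BP component beat series.  A pulse waveform
    is then built whose beat maxima/minima equal the systolic/diastolic
    targets exactly and whose beat mean hits the mean target by inverting the
    kernel's systolic fraction per beat.

    Returns the augmented recording and the ground-truth table.
    """
    pulse = pulse or PulseShapeParams()
    truths = list(truths)
    if bp_recording.bp is None:
        raise ValidationError("bp channel is required")
    if forcing_freq is None:
        forcing_freq = bp_recording.ssm_frequency or 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    by_vessel: dict[str, dict[str, TransferTruth]] = {}
    for tr in truths:
        by_vessel.setdefault(tr.vessel, {})[tr.component] = tr
    for vessel, comps in by_vessel.items():
        if set(comps) != set(COMPONENTS):
            raise ValidationError(
                f"vessel {vessel!r} needs truths for all of {COMPONENTS}"
            )

    bt = bp_recording.truth_beats
    if bt is None:
        # Recover per-beat BP levels from the trace itself.
        from . import beats as _beats

        onset_times = _beats.detect_beats(bp_recording.bp, bp_recording.sample_rate)
        table = _beats.decompose_beats(
            bp_recording.bp, onset_times, bp_recording.sample_rate
        )
        bt = pd.DataFrame(
            {
                "onset_time": table["beat_onset_time"].to_numpy(),
                "rr_interval": table["rr_interval"].to_numpy(),
                "bp_diastolic": table["diastolic"].to_numpy(),
                "bp_systolic": table["systolic"].to_numpy(),
                "bp_mean": table["mean"].to_numpy(),
            }
        )
        onsets = np.concatenate(
            [bt["onset_time"].to_numpy(), [bt["onset_time"].iloc[-1] + bt["rr_interval"].iloc[-1]]]
        )
    else:
        onsets = np.concatenate(
            [bt["onset_time"].to_numpy(), [bt["onset_time"].iloc[-1] + bt["rr_interval"].iloc[-1]]]
        )

    t_beat = bt["onset_time"].to_numpy()
    rr = bt["rr_interval"].to_numpy()
    bp_series = {
        "diastolic": bt["bp_diastolic"].to_numpy(),
        "mean": bt["bp_mean"].to_numpy(),
        "systolic": bt["bp_systolic"].to_numpy(),
    }

    rec = replace(bp_recording)
    rows = []
    for vessel, comps in by_vessel.items():
        targets: dict[str, np.ndarray] = {}
        for comp in COMPONENTS:
            tr = comps[comp]
            if forcing_freq > 0:
                amp, phi0 = _fit_sinusoid(t_beat, bp_series[comp], forcing_freq)
                osc = amp * np.sin(
                    2.0 * np.pi * forcing_freq * t_beat + phi0 + tr.phase_true
                )
            else:
                osc = np.zeros_like(t_beat)
            noise = rng.normal(0.0, noise_sd, size=t_beat.size) if noise_sd > 0 else 0.0
            targets[comp] = tr.baseline_velocity + tr.gain_true * osc + noise
            rows.append(
                {
                    "vessel": vessel,
                    "component": comp,
                    "gain_true": tr.gain_true,
                    "phase_true": tr.phase_true,
                    "baseline_velocity": tr.baseline_velocity,
                }
            )
        v_dia, v_mean, v_sys = targets["diastolic"], targets["mean"], targets["systolic"]
        if np.any(v_sys <= v_dia):
            raise ValidationError(
                f"vessel {vessel!r}: systolic targets must exceed diastolic targets; "
                "reduce forcing amplitude or noise, or separate the baselines"
            )
        m_req = (v_mean - v_dia) / (v_sys - v_dia)
        ledge = _ledge_fractions(v_dia, v_sys, pulse.end_diastolic_offset)
        sf = _invert_mean_fraction(m_req, pulse.decay_rate * rr, ledge)
        wave = _pulse_train(
            rec.time, onsets, v_dia, v_sys, sf, pulse.decay_rate, ledge
        )
        if vessel == "MCA":
            rec.mcav = wave
        else:
            rec.pcav = wave

    return rec, pd.DataFrame(rows)


def simulate_petco2(
    stage_target: float,
    breath_rate: float = 15.0,
    duration: float = 240.0,
    sample_rate: float = 250.0,
    jitter_sd: float = 0.3,
    seed: int | np.random.Generator = 0,
    depth: float = 8.0,
) -> np.ndarray:
    """Breath-wise PETCO2 trace clamped at ``stage_target``.

    Each breath is a raised-cosine excursion from ``stage_target - depth`` up
    to a per-breath peak of ``stage_target`` plus Gaussian jitter, emulating
    end-tidal clamping that holds breath peaks within 1 mmHg of the target.
    """
    if stage_target <= 0:
        raise ValidationError("stage_target must be positive")
    if not 6.0 <= breath_rate <= 40.0:
        raise ValidationError("breath_rate must lie in [6, 40] breaths/min")
    if duration <= 0 or sample_rate <= 0:
        raise ValidationError("duration and sample_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mean_tb = 60.0 / breath_rate
    n_breaths = int(np.ceil(duration / mean_tb)) + 2
    tb = mean_tb * (1.0 + np.clip(rng.normal(0.0, 0.03, n_breaths), -0.15, 0.15))
    bounds = np.concatenate([[0.0], np.cumsum(tb)])
    peaks = np.full(n_breaths, float(stage_target))
    if jitter_sd > 0:
        peaks += rng.normal(0.0, jitter_sd, n_breaths)

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    k = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, n_breaths - 1)
    u = (t - bounds[k]) / tb[k]
    low = stage_target - depth
    return low + (peaks[k] - low) * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


# Stage-level defaults for the injected transfer truths, loosely calibrated to
# reported squat-stand TFA magnitudes: phase decreases and absolute gain tends
# to increase from hypocapnia through eucapnia to hypercapnia, and baseline
# velocity rises with CO2.  These are plausible simulation conditions, not
# reproductions of any measured cohort.
# (vessel, component, freq) -> {stage: (gain cm/s/mmHg, phase rad)}
_STAGE_GAIN_PHASE: dict[tuple[str, str, float], dict[str, tuple[float, float]]] = {
    ("MCA", "diastolic", 0.05): {"hypocapnia": (0.77, 0.68), "eucapnia": (0.98, 0.52), "hypercapnia": (1.12, 0.22)},
    ("MCA", "diastolic", 0.10): {"hypocapnia": (1.26, 0.52), "eucapnia": (1.26, 0.38), "hypercapnia": (1.36, 0.23)},
    ("MCA", "mean", 0.05): {"hypocapnia": (0.54, 0.85), "eucapnia": (0.79, 0.47), "hypercapnia": (0.99, 0.19)},
    ("MCA", "mean", 0.10): {"hypocapnia": (0.97, 0.60), "eucapnia": (1.09, 0.40), "hypercapnia": (1.10, 0.19)},
    ("MCA", "systolic", 0.05): {"hypocapnia": (0.40, 1.93), "eucapnia": (0.46, 0.93), "hypercapnia": (0.53, 0.41)},
    ("MCA", "systolic", 0.10): {"hypocapnia": (0.60, 1.25), "eucapnia": (0.55, 0.84), "hypercapnia": (0.65, 0.49)},
    ("PCA", "diastolic", 0.05): {"hypocapnia": (0.62, 0.62), "eucapnia": (0.68, 0.44), "hypercapnia": (0.66, 0.22)},
    ("PCA", "diastolic", 0.10): {"hypocapnia": (0.98, 0.48), "eucapnia": (0.94, 0.41), "hypercapnia": (0.85, 0.25)},
    ("PCA", "mean", 0.05): {"hypocapnia": (0.38, 0.73), "eucapnia": (0.49, 0.43), "hypercapnia": (0.56, 0.19)},
    ("PCA", "mean", 0.10): {"hypocapnia": (0.67, 0.58), "eucapnia": (0.69, 0.40), "hypercapnia": (0.64, 0.23)},
    ("PCA", "systolic", 0.05): {"hypocapnia": (0.20, 1.83), "eucapnia": (0.28, 0.93), "hypercapnia": (0.33, 0.35)},
    ("PCA", "systolic", 0.10): {"hypocapnia": (0.29, 1.32), "eucapnia": (0.37, 0.89), "hypercapnia": (0.43, 0.56)},
}

#: Eucapnic baseline velocities (cm/s) per vessel and component.
_BASELINE_VELOCITY = {
    ("MCA", "diastolic"): 45.0,
    ("MCA", "mean"): 65.0,
    ("MCA", "systolic"): 95.0,
    ("PCA", "diastolic"): 28.0,
    ("PCA", "mean"): 40.0,
    ("PCA", "systolic"): 60.0,
}

#: CO2 vasoreactivity of baseline velocity relative to eucapnia.
_STAGE_VELOCITY_FACTOR = {"hypocapnia": 0.80, "eucapnia": 1.00, "hypercapnia": 1.25}


def default_transfer_truths(
    stage: str, ssm_frequency: float, sex: str = "female"
) -> list[TransferTruth]:
    """Population-level transfer truths for one stage/frequency cell."""
    freq = 0.05 if abs(ssm_frequency - 0.05) < 0.02 else 0.10
    sex_factor = 1.05 if sex == "female" else 0.95
    out = []
    for vessel in VESSELS:
        for comp in COMPONENTS:
            gain, phase = _STAGE_GAIN_PHASE[(vessel, comp, freq)][stage]
            base = (
                _BASELINE_VELOCITY[(vessel, comp)]
                * _STAGE_VELOCITY_FACTOR[stage]
                * sex_factor
            )
            out.append(TransferTruth(vessel, comp, gain, phase, base))
    return out


def transitions_per_minute(ssm_freq: float) -> float:
    """Posture transitions per minute for a squat-stand pacing frequency.

    One squat-stand cycle contains two transitions (down and up), so pacing at
    ``f`` Hz requires ``2 * f * 60`` transitions per minute -- the metronome
    setting of the protocol (6/min at 0.05 Hz, 12/min at 0.10 Hz).
    """
    if ssm_freq <= 0:
        raise ValidationError("ssm_freq must be positive")
    return 2.0 * ssm_freq * 60.0


def generate_cohort(spec: CohortSpec) -> tuple[list[RawRecording], pd.DataFrame]:
    """Generate one recording per participant x stage x pacing frequency.

    Participant-level heterogeneity (heart rate, pressures, multiplicative
    gain/baseline factors and additive phase offsets) is drawn once per
    participant from the cohort seed, so the same participant keeps coherent
    physiology across stages.  Returns the recordings and the ground-truth
    table of every injected transfer.
    """
    root = np.random.SeedSequence(spec.seed)
    n_total = spec.n_female + spec.n_male
    part_ss, rec_ss = root.spawn(2)
    part_rngs = [np.random.default_rng(s) for s in part_ss.spawn(n_total)]
    rec_children = rec_ss.spawn(n_total * len(spec.stages) * len(spec.ssm_frequencies))

    recordings: list[RawRecording] = []
    truth_rows: list[dict] = []
    targets = spec.targets
    rec_idx = 0
    for p in range(n_total):
        sex = "female" if p < spec.n_female else "male"
        pid = f"F{p + 1:02d}" if sex == "female" else f"M{p - spec.n_female + 1:02d}"
        prng = part_rngs[p]
        hr = prng.uniform(80.0, 105.0)
        dbp = float(np.clip(prng.normal(75.0, 6.0), 60.0, 95.0))
        pp = float(np.clip(prng.normal(45.0, 6.0), 30.0, 65.0))
        gain_factor = float(np.clip(prng.normal(1.0, 0.08), 0.75, 1.25))
        base_factor = float(np.clip(prng.normal(1.0, 0.08), 0.75, 1.25))
        phase_offset = float(np.clip(prng.normal(0.0, 0.05), -0.15, 0.15))

        for stage in spec.stages:
            for freq in spec.ssm_frequencies:
                child = rec_children[rec_idx]
                rec_idx += 1
                rng = np.random.default_rng(child)
                rec = simulate_bp_waveform(
                    hr=hr,
                    sbp=dbp + pp,
                    dbp=dbp,
                    forcing_freq=freq,
                    forcing_amp=spec.forcing_amplitude,
                    duration=spec.duration,
                    sample_rate=spec.sample_rate,
                    seed=rng,
                )
                truths = [
                    replace(
                        tr,
                        gain_true=tr.gain_true * gain_factor,
                        phase_true=tr.phase_true + phase_offset,
                        baseline_velocity=tr.baseline_velocity * base_factor,
                    )
                    for tr in default_transfer_truths(stage, freq, sex)
                ]
                rec, truth = apply_transfer(
                    rec, truths, forcing_freq=freq, noise_sd=spec.noise_sd, seed=rng
                )
                rec.petco2 = simulate_petco2(
                    targets[stage],
                    duration=spec.duration,
                    sample_rate=spec.sample_rate,
                    seed=rng,
                )
                rec.participant = pid
                rec.sex = sex
                rec.stage = stage
                rec.ssm_frequency = freq
                rec.seed = spec.seed
                recordings.append(rec)
                for _, row in truth.iterrows():
                    truth_rows.append(
                        {
                            "participant": pid,
                            "sex": sex,
                            "stage": stage,
                            "ssm_frequency_hz": freq,
                            "vessel": row["vessel"],
                            "component": row["component"],
                            "gain_true": row["gain_true"],
                            "phase_true": row["phase_true"],
                            "baseline_velocity": row["baseline_velocity"],
                        }
                    )
    return recordings, pd.DataFrame(truth_rows)
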