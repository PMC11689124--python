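"""Beat detection and cardiac-cycle decomposition.

Beats are detected from the pulsatile pressure trace at the pressure foot
(the local minimum preceding each systolic upstroke); the same boundaries are
then applied to the velocity channels so that pressure and velocity are
decomposed over identical cardiac cycles.  Each half-open beat
``[onset_i, onset_{i+1})`` yields a systolic (maximum), diastolic (minimum)
and mean (time-average) value, plus the R-R interval and instantaneous heart
rate.  Outlying systolic peaks are repaired by spline interpolation across
neighbouring beats, mirroring the manual artifact correction used on real
recordings, and breath-to-breath PETCO2 peaks are extracted analogously.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .errors import (
    FlatTraceError,
    MassArtifactError,
    TooFewBeatsError,
    ValidationError,
)

__all__ = [
    "detect_beats",
    "decompose_beats",
    "flag_and_correct_artifacts",
    "extract_breath_peaks",
]

#: Columns of a beat table.
BEAT_COLUMNS = [
    "beat_onset_time",
    "systolic",
    "diastolic",
    "mean",
    "rr_interval",
    "heart_rate",
    "corrected_flag",
]


def detect_beats(
    trace: np.ndarray,
    sample_rate: float,
    hr_bounds: tuple[float, float] = (40.0, 180.0),
) -> np.ndarray:
    """Locate beat onsets (pressure feet) in a pulsatile trace.

    Systolic peaks are found first with a refractory period of ``60/hr_max``
    seconds and a prominence floor of a quarter of the trace's robust range;
    each onset is then the sample of minimum value between consecutive peaks
    (or in the pre-peak window for the first beat).

    Returns onset times in seconds.  Raises :class:`FlatTraceError` for a
    constant trace and :class:`TooFewBeatsError` when fewer than 8 beats are
    found (too short for spectral analysis).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < int(10 * sample_rate):
        raise ValidationError("trace must be at least 10 s long")
    hr_min, hr_max = hr_bounds
    if not (30.0 <= hr_min < hr_max <= 220.0):
        raise ValidationError("hr_bounds must satisfy 30 <= lo < hi <= 220")
    lo, hi = np.percentile(trace, [5, 95])
    if hi - lo < 1e-9 * max(1.0, abs(hi)):
        raise FlatTraceError("trace has no pulsatile variation")

    refractory = max(1, int(round(60.0 / hr_max * sample_rate)))
    peaks, _ = find_peaks(trace, distance=refractory, prominence=0.25 * (hi - lo))
    if peaks.size < 9:
        raise TooFewBeatsError(f"only {max(peaks.size - 1, 0)} beats detected; need >= 8")

    onsets = np.empty(peaks.size, dtype=int)
    pre = max(1, int(round(60.0 / hr_min * sample_rate)))
    start = max(0, peaks[0] - pre)
    onsets[0] = start + int(np.argmin(trace[start : peaks[0] + 1]))
    for i in range(1, peaks.size):
        seg = trace[peaks[i - 1] : peaks[i] + 1]
        onsets[i] = peaks[i - 1] + int(np.argmin(seg))
    onsets = np.unique(onsets)
    if onsets.size < 9:
        raise TooFewBeatsError(f"only {onsets.size - 1} beats detected; need >= 8")
    return onsets / sample_rate


def decompose_beats(
    trace: np.ndarray,
    onset_times: np.ndarray,
    sample_rate: float,
) -> pd.DataFrame:
    """Per-beat systolic/diastolic/mean decomposition over given boundaries.

    Beat ``i`` spans the half-open sample interval ``[onset_i, onset_{i+1})``;
    its systolic value is the maximum sample, diastolic the minimum, mean the
    arithmetic average, and the R-R interval is ``onset_{i+1} - onset_i``.
    The final onset only closes the last beat.
    """
    trace = np.asarray(trace, dtype=float)
    onset_times = np.asarray(onset_times, dtype=float)
    if onset_times.size < 2:
        raise ValidationError("need at least 2 beat boundaries")
    if np.any(np.diff(onset_times) <= 0):
        raise ValidationError("beat boundaries must be strictly increasing")

    idx = np.round(onset_times * sample_rate).astype(int)
    idx = np.clip(idx, 0, trace.size)
    starts, stops = idx[:-1], idx[1:]
    if np.any(stops <= starts):
        raise ValidationError("beat boundaries collapse at this sample rate")

    sys_ = np.maximum.reduceat(trace, starts)
    dia = np.minimum.reduceat(trace, starts)
    csum = np.concatenate([[0.0], np.cumsum(trace)])
    mean = (csum[stops] - csum[starts]) / (stops - starts)
    # reduceat runs to the end of the array from the last index; restrict it
    last = slice(starts[-1], stops[-1])
    sys_[-1] = trace[last].max()
    dia[-1] = trace[last].min()

    rr = np.diff(onset_times)
    table = pd.DataFrame(
        {
            "beat_onset_time": onset_times[:-1],
            "systolic": sys_,
            "diastolic": dia,
            "mean": mean,
            "rr_interval": rr,
            "heart_rate": 60.0 / rr,
            "corrected_flag": np.zeros(rr.size, dtype=bool),
        }
    )
    bad = ~((table["diastolic"] <= table["mean"]) & (table["mean"] <= table["systolic"]))
    if bad.any():
        raise ValidationError("beat decomposition violated diastolic <= mean <= systolic")
    return table


def flag_and_correct_artifacts(
    table: pd.DataFrame,
    z_threshold: float = 4.0,
    window: int = 11,
    mass_fraction: float = 0.2,
) -> tuple[pd.DataFrame, float]:
    """Repair outlying systolic peaks by interpolation across neighbours.

    A beat is flagged when its systolic value deviates from the centred
    rolling median (``window`` beats) by more than ``z_threshold`` robust
    standard deviations.  The robust scale is the largest of 1.4826 x the
    median absolute rolling-median residual, the median absolute beat-to-beat
    systolic difference, and 0.5% of the median systolic level.  The last two
    floors matter on smooth low-noise series: inside monotone stretches the
    centre of an odd window *is* its median, so residual-based dispersion
    collapses to zero and legitimate slow oscillation (the squat-stand
    forcing itself) would self-flag.  Flagged systolic values are replaced by
    a cubic spline through the unflagged beats.

    Returns the corrected table (a copy) and the corrected fraction of beats.
    Raises :class:`MassArtifactError` when more than ``mass_fraction`` of the
    beats flag -- isolated spikes should affect well under 1% of beats, so a
    mass flagging indicates a systematic signal change the screen must not
    silently rewrite.
    """
    if z_threshold <= 0:
        raise ValidationError("z_threshold must be positive")
    if len(table) < 5:
        raise ValidationError("need at least 5 beats for artifact screening")

    out = table.copy()
    sys_ = out["systolic"].to_numpy(dtype=float)
    med = (
        pd.Series(sys_)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    resid = sys_ - med
    scale = max(
        1.4826 * float(np.median(np.abs(resid))),
        float(np.median(np.abs(np.diff(sys_)))),
        0.005 * abs(float(np.median(sys_))),
    )
    flagged = np.abs(resid) > z_threshold * scale
    frac = float(flagged.mean())
    if frac > mass_fraction:
        raise MassArtifactError(
            f"{frac:.0%} of beats flagged as artifacts; refusing mass correction"
        )
    if flagged.any():
        t = out["beat_onset_time"].to_numpy()
        good = ~flagged
        spline = CubicSpline(t[good], sys_[good])
        sys_[flagged] = spline(t[flagged])
        # Repair cannot push the peak below the beat mean.
        sys_[flagged] = np.maximum(sys_[flagged], out["mean"].to_numpy()[flagged])
        out["systolic"] = sys_
        out["corrected_flag"] = out["corrected_flag"].to_numpy() | flagged
    return out, frac


def extract_breath_peaks(
    petco2: np.ndarray,
    sample_rate: float,
    breath_bounds: tuple[float, float] = (6.0, 40.0),
) -> pd.DataFrame:
    """Breath-to-breath PETCO2 peak extraction.

    Peaks are located with a refractory period of ``60/breath_max`` seconds
    and a prominence floor of a quarter of the robust trace range.  The
    returned frame has columns ``breath_time`` and ``petco2_peak``; the
    per-recording mean and SD of the peaks are stored in ``DataFrame.attrs``.
    """
    petco2 = np.asarray(petco2, dtype=float)
    if petco2.size < int(30 * sample_rate):
        raise ValidationError("PETCO2 trace must be at least 30 s long")
    lo, hi = np.percentile(petco2, [5, 95])
    if hi - lo < 1e-9 * max(1.0, abs(hi)):
        raise FlatTraceError("PETCO2 trace has no breath-wise variation")
    _, breath_max = breath_bounds
    refractory = max(1, int(round(60.0 / breath_max * sample_rate)))
    peaks, _ = find_peaks(petco2, distance=refractory, prominence=0.25 * (hi - lo))
    if peaks.size == 0:
        raise FlatTraceError("no breath peaks found")
    out = pd.DataFrame(
        {"breath_time": peaks / sample_rate, "petco2_peak": petco2[peaks]}
    )
    out.attrs["mean_peak"] = float(out["petco2_peak"].mean())
    out.attrs["sd_peak"] = float(out["petco2_peak"].std(ddof=1)) if len(out) > 1 else 0.0
    return out
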