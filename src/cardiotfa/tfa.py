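"""Transfer function analysis of beat-to-beat series.

The beat-to-beat component series (systolic, diastolic or mean pressure and
velocity) are cubic-spline resampled onto a uniform 4 Hz grid, segmented into
80-s Hanning windows at 50% overlap with per-window linear detrending, and
averaged into Welch auto- and cross-spectral densities.  From these come the
standard autoregulation metrics: magnitude-squared coherence, phase (radians,
positive when velocity leads pressure), absolute gain (cm/s/mmHg) and
normalized gain (%/mmHg), read off at the squat-stand pacing frequencies.

With 80-s windows at 4 Hz the frequency resolution is 0.0125 Hz, so the 0.05
and 0.10 Hz point estimates fall on exact spectral bins (bins 4 and 8) and are
single-bin reads rather than band averages.  A point estimate is flagged, not
dropped, when its coherence falls below the critical value (default 0.46, the
alpha = 0.01 criterion for five windows recommended for standardized
autoregulation analysis); phase is reported in (-pi, pi] without unwrapping
and wraparound between adjacent bins is only flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import ValidationError

__all__ = [
    "UniformSeries",
    "WelchConfig",
    "SpectralEstimates",
    "PointEstimate",
    "spline_resample",
    "segment_windows",
    "welch_spectra",
    "point_metrics",
    "detect_wraparound",
    "CRITICAL_COHERENCE",
]

#: Critical magnitude-squared coherence (alpha = 0.01, five windows); a
#: looked-up convention constant, not re-derived here.
CRITICAL_COHERENCE = 0.46


@dataclass
class UniformSeries:
    """One cardiac-cycle component series on a uniform time grid."""

    values: np.ndarray
    rate: float = 4.0  # Hz
    component: str = "mean"
    channel: str = "BP"
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("series contains non-finite values")

    @property
    def duration(self) -> float:
        return self.values.size / self.rate


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimation settings (defaults: 80-s Hanning windows, 50% overlap,
    per-window linear detrend, spectral smoothing off, 240-s records)."""

    window_length: float = 80.0  # s
    overlap_fraction: float = 0.5
    detrend: str = "linear"  # linear | mean | none
    smooth_spectra: bool = False
    segment_length_required: float = 240.0  # s

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValidationError("overlap_fraction must lie in [0, 1)")
        if self.window_length <= 0:
            raise ValidationError("window_length must be positive")
        if self.detrend not in ("linear", "mean", "none"):
            raise ValidationError("detrend must be linear, mean or none")

    def nperseg(self, rate: float) -> int:
        return int(round(self.window_length * rate))

    def step(self, rate: float) -> int:
        n = self.nperseg(rate)
        return max(1, int(round(n * (1.0 - self.overlap_fraction))))

    def n_windows(self, n_samples: int, rate: float) -> int:
        n = self.nperseg(rate)
        if n > n_samples:
            raise ValidationError("window is longer than the record")
        return (n_samples - n) // self.step(rate) + 1


@dataclass
class SpectralEstimates:
    """Full-spectrum Welch outputs for one BP -> velocity component pair."""

    freqs: np.ndarray  # Hz
    psd_input: np.ndarray  # mmHg^2/Hz
    psd_output: np.ndarray  # (cm/s)^2/Hz
    cross_spectrum: np.ndarray  # complex
    coherence: np.ndarray  # magnitude-squared, in [0, 1]
    phase: np.ndarray  # rad, (-pi, pi]
    gain: np.ndarray  # cm/s/mmHg
    n_windows: int
    component: str = "mean"
    vessel: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq_hz": self.freqs,
                "psd_bp": self.psd_input,
                "psd_cbv": self.psd_output,
                "coherence": self.coherence,
                "phase_rad": self.phase,
                "gain": self.gain,
            }
        )


@dataclass
class PointEstimate:
    """Single-frequency TFA metrics with the coherence-criterion flag."""

    frequency: float
    coherence: float
    phase: float
    gain: float
    ngain: float
    psd_input: float
    psd_output: float
    coherence_pass: bool
    wraparound_flag: bool
    n_windows: int


def spline_resample(
    beat_table: pd.DataFrame,
    component: str,
    rate: float = 4.0,
    t_start: float | None = None,
    duration: float | None = None,
    channel: str = "BP",
) -> UniformSeries:
    """Cubic-spline resample a beat-to-beat component series to a uniform grid.

    The (onset time, value) points are interpolated with a natural cubic
    spline evaluated every ``1/rate`` seconds; grid points before the first or
    after the last beat are held at the nearest beat value (no extrapolation).
    Passing ``t_start``/``duration`` lets the caller pin the grid to the full
    recording span so window arithmetic sees the nominal record length.
    """
    if component not in ("diastolic", "mean", "systolic"):
        raise ValidationError(f"unknown component {component!r}")
    t = beat_table["beat_onset_time"].to_numpy(dtype=float)
    x = beat_table[component].to_numpy(dtype=float)
    if t.size < 8:
        raise ValidationError("need at least 8 beats to resample")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("beat times must be strictly increasing (no duplicates)")

    if t_start is None:
        t_start = float(t[0])
    if duration is None:
        duration = float(t[-1] - t_start)
    n = int(round(duration * rate))
    if n < 2:
        raise ValidationError("resampled series would be shorter than 2 samples")
    grid = t_start + np.arange(n) / rate
    spline = CubicSpline(t, x)
    values = spline(np.clip(grid, t[0], t[-1]))
    return UniformSeries(values, rate=rate, component=component, channel=channel, t_start=t_start)


def _hanning(n: int) -> np.ndarray:
    """Periodic (DFT-even) Hanning taper."""
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)


def segment_windows(series: UniformSeries, cfg: WelchConfig) -> list[np.ndarray]:
    """Split a series into detrended, Hanning-tapered windows.

    Windows start every ``window_length * (1 - overlap)`` seconds, so a record
    of duration D yields ``floor((D - L) / (L*(1-overlap))) + 1`` windows; a
    240-s record at the 80-s / 50% defaults yields five.
    """
    n = cfg.nperseg(series.rate)
    count = cfg.n_windows(series.values.size, series.rate)
    step = cfg.step(series.rate)
    taper = _hanning(n)
    out = []
    for k in range(count):
        seg = series.values[k * step : k * step + n]
        if cfg.detrend == "linear":
            seg = sps.detrend(seg, type="linear")
        elif cfg.detrend == "mean":
            seg = seg - seg.mean()
        out.append(seg * taper)
    return out


def _triangular_smooth(x: np.ndarray) -> np.ndarray:
    """3-point triangular smoother over frequency with edge replication."""
    padded = np.concatenate([x[:1], x, x[-1:]])
    return 0.25 * padded[:-2] + 0.5 * padded[1:-1] + 0.25 * padded[2:]


def welch_spectra(
    x: UniformSeries,
    y: UniformSeries,
    cfg: WelchConfig | None = None,
) -> SpectralEstimates:
    """Welch auto/cross spectral densities and TFA metrics for a series pair.

    Per-window DFTs of the detrended, Hanning-tapered segments are averaged
    with a common density normalization (the PSD of unit-variance white noise
    integrates to one):  ``Pxx = mean|X|^2 c``, ``Pyy = mean|Y|^2 c`` and
    ``Sxy = mean(conj(X) Y) c``.  Coherence is ``|Sxy|^2 / (Pxx Pyy)``, gain
    ``|Sxy| / Pxx`` and phase ``arg Sxy`` -- positive when y leads x.
    """
    cfg = cfg or WelchConfig()
    if x.rate != y.rate or x.values.size != y.values.size:
        raise ValidationError("x and y must share rate and length")
    n_windows = cfg.n_windows(x.values.size, x.rate)
    if n_windows < 2:
        raise ValidationError("need at least 2 windows; coherence is undefined for 1")

    nperseg = cfg.nperseg(x.rate)
    noverlap = nperseg - cfg.step(x.rate)
    detrend = False if cfg.detrend == "none" else ("constant" if cfg.detrend == "mean" else "linear")
    kw = dict(
        fs=x.rate,
        window=_hanning(nperseg),
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=detrend,
        scaling="density",
        average="mean",
    )
    freqs, pxx = sps.welch(x.values, **kw)
    _, pyy = sps.welch(y.values, **kw)
    _, sxy = sps.csd(x.values, y.values, **kw)

    if cfg.smooth_spectra:
        pxx = _triangular_smooth(pxx)
        pyy = _triangular_smooth(pyy)
        sxy = _triangular_smooth(sxy.real) + 1j * _triangular_smooth(sxy.imag)

    denom = pxx * pyy
    with np.errstate(divide="ignore", invalid="ignore"):
        coherence = np.where(denom > 0, np.abs(sxy) ** 2 / denom, 0.0)
        gain = np.where(pxx > 0, np.abs(sxy) / pxx, 0.0)
    coherence = np.clip(coherence, 0.0, 1.0)
    phase = np.angle(sxy)
    return SpectralEstimates(
        freqs=freqs,
        psd_input=pxx,
        psd_output=pyy,
        cross_spectrum=sxy,
        coherence=coherence,
        phase=phase,
        gain=gain,
        n_windows=n_windows,
        component=x.component,
        vessel=y.channel,
    )


def _band_for_frequency(f0: float, df: float) -> tuple[float, float]:
    """Autoregulation band containing f0: very-low (0.02-0.07 Hz), low
    (0.07-0.20 Hz), else two bins either side."""
    if 0.02 <= f0 < 0.07:
        return (0.02, 0.07)
    if 0.07 <= f0 < 0.20:
        return (0.07, 0.20)
    return (f0 - 2 * df, f0 + 2 * df)


def point_metrics(
    spectra: SpectralEstimates,
    f0: float,
    mean_output_level: float,
    critical_coherence: float = CRITICAL_COHERENCE,
) -> PointEstimate:
    """TFA metrics at a single frequency point estimate.

    Values are read at the spectral bin nearest ``f0`` (exact when the bin
    spacing divides f0).  Normalized gain divides the absolute gain by the
    output series' own segment mean, expressed in %/mmHg.  Estimates whose
    coherence falls below ``critical_coherence`` are flagged via
    ``coherence_pass``, never dropped.  The wraparound screen covers the
    autoregulation band containing ``f0`` but only its bins that meet the
    coherence criterion -- phase is not interpretable where coherence is
    inadequate, and at bins without appreciable power its angle is noise.
    """
    if mean_output_level <= 0:
        raise ValidationError("mean_output_level must be positive")
    nyquist = spectra.freqs[-1]
    if f0 > nyquist or f0 < spectra.freqs[0]:
        raise ValidationError(f"f0={f0} Hz outside the resolved band")
    idx = int(np.argmin(np.abs(spectra.freqs - f0)))
    df = float(spectra.freqs[1] - spectra.freqs[0])
    band = _band_for_frequency(f0, df)
    in_band = (spectra.freqs >= band[0] - 1e-12) & (spectra.freqs <= band[1] + 1e-12)
    usable = in_band & (spectra.coherence >= critical_coherence)
    wrap = False
    if usable.sum() >= 2:
        f_use = spectra.freqs[usable]
        wrap = detect_wraparound(f_use, spectra.phase[usable], (f_use[0], f_use[-1]))
    gain = float(spectra.gain[idx])
    return PointEstimate(
        frequency=float(spectra.freqs[idx]),
        coherence=float(spectra.coherence[idx]),
        phase=float(spectra.phase[idx]),
        gain=gain,
        ngain=gain / mean_output_level * 100.0,
        psd_input=float(spectra.psd_input[idx]),
        psd_output=float(spectra.psd_output[idx]),
        coherence_pass=bool(spectra.coherence[idx] >= critical_coherence),
        wraparound_flag=wrap,
        n_windows=spectra.n_windows,
    )


def detect_wraparound(
    freqs: np.ndarray,
    phase: np.ndarray,
    band: tuple[float, float],
) -> bool:
    """True iff any adjacent-bin phase jump within ``band`` exceeds pi.

    A single-bin band has no adjacent pair and returns False; an empty band is
    an error.
    """
    freqs = np.asarray(freqs, dtype=float)
    phase = np.asarray(phase, dtype=float)
    lo, hi = band
    mask = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    if not mask.any():
        raise ValidationError("band contains no spectral bins")
    p = phase[mask]
    if p.size < 2:
        return False
    return bool(np.any(np.abs(np.diff(p)) > np.pi))
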