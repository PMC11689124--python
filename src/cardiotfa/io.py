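"""Reading and writing the package's plain-text formats.

Recordings travel as CSV with the fixed header
``time_s,bp_mmhg,mcav_cms,pcav_cms,petco2_mmhg`` plus a YAML sidecar
(``<name>.meta.yaml``) holding participant, sex, stage, pacing frequency,
sample rate and seed.  Beat, breath, truth and metric tables are TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    MissingColumnError,
    NonFiniteValueError,
    NonMonotoneTimeError,
    NonUniformSamplingError,
)
from .synthdata import RawRecording

__all__ = ["read_recording", "write_recording", "sidecar_path"]

RECORDING_COLUMNS = ["time_s", "bp_mmhg", "mcav_cms", "pcav_cms", "petco2_mmhg"]
_CHANNEL_OF = {"bp_mmhg": "bp", "mcav_cms": "mcav", "pcav_cms": "pcav", "petco2_mmhg": "petco2"}


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_recording(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as CSV plus a YAML metadata sidecar."""
    path = Path(path)
    n = rec.time.size
    data = {"time_s": rec.time, "bp_mmhg": rec.bp}
    for col, ch in (("mcav_cms", rec.mcav), ("pcav_cms", rec.pcav), ("petco2_mmhg", rec.petco2)):
        data[col] = ch if ch is not None else np.full(n, np.nan)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")
    meta = {
        "participant": rec.participant,
        "sex": rec.sex,
        "stage": rec.stage,
        "ssm_frequency_hz": rec.ssm_frequency,
        "sample_rate_hz": rec.sample_rate,
        "seed": rec.seed,
    }
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_recording(path: str | Path) -> RawRecording:
    """Read and validate a recording CSV (and its sidecar, when present).

    Raises named errors for a missing column, a non-monotone time column,
    sample spacing that varies beyond 1 microsecond, or non-finite channel
    values.  All-empty optional channels (written as NaN) are allowed and
    read back as absent.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in RECORDING_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(f"{path.name}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise NonMonotoneTimeError(f"{path.name}: time column is not strictly increasing")
    if np.ptp(dt) > 1e-6:
        raise NonUniformSamplingError(
            f"{path.name}: sampling step varies by {np.ptp(dt):.2e} s (> 1e-6 s)"
        )
    sample_rate = 1.0 / float(np.median(dt))

    channels: dict[str, np.ndarray | None] = {}
    for col, name in _CHANNEL_OF.items():
        x = df[col].to_numpy(dtype=float)
        if np.all(np.isnan(x)):
            channels[name] = None
            continue
        if np.any(~np.isfinite(x)):
            raise NonFiniteValueError(f"{path.name}: non-finite values in {col!r}")
        channels[name] = x
    if channels["bp"] is None:
        raise NonFiniteValueError(f"{path.name}: bp channel is entirely missing")

    meta = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta = yaml.safe_load(sp.read_text()) or {}
    return RawRecording(
        time=t - t[0],
        bp=channels["bp"],
        mcav=channels["mcav"],
        pcav=channels["pcav"],
        petco2=channels["petco2"],
        sample_rate=float(meta.get("sample_rate_hz") or sample_rate),
        participant=str(meta.get("participant", "P01")),
        sex=str(meta.get("sex", "female")),
        stage=str(meta.get("stage", "eucapnia")),
        ssm_frequency=meta.get("ssm_frequency_hz"),
        seed=meta.get("seed"),
    )
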