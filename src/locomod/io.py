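"""Readers and writers for the package's plain-text interchange formats.

All tabular files are comma-separated with a mandatory header row and '.'
decimals, so a write→read round trip is bit-exact to the printed precision.
Audio is 16-bit PCM WAV via :mod:`scipy.io.wavfile`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .core import (
    AudioTrace,
    BehaviorSegments,
    ParseError,
    SpeedTrace,
    SpikeTrain,
    ToneTrialTable,
    ValidationError,
)

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_speed",
    "write_speed",
    "read_trials",
    "write_trials",
    "read_segments",
    "write_segments",
    "read_onsets",
    "write_onsets",
    "read_audio",
    "write_audio",
    "read_config",
    "write_config",
]

_FLOAT_FMT = "%.9f"


def _read_csv(path, columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # includes the offending line no.
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for c in columns:
        if c in ("unit_id", "label", "site_id"):
            continue
        col = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[col.isna() & df[c].notna()]
        if len(bad):
            # +2: header row plus 1-based numbering
            raise ParseError(f"{path}: malformed value in line {bad[0] + 2}")
        df[c] = col
    return df


def read_spikes(path, duration: float | None = None) -> list[SpikeTrain]:
    """Read ``spikes.csv`` (unit_id,time_s) into sorted spike trains.

    ``duration`` defaults to the latest spike time in the file; an empty
    file yields an empty collection.
    """
    df = _read_csv(path, ["unit_id", "time_s"])
    if df.empty:
        return []
    if df["time_s"].isna().any():
        row = int(df.index[df["time_s"].isna()][0]) + 2
        raise ParseError(f"{path}: malformed value in line {row}")
    if (df["time_s"] < 0).any():
        raise ValidationError(f"{path}: negative spike time")
    if duration is None:
        duration = float(df["time_s"].max())
        duration = duration if duration > 0 else 1.0
    trains = []
    for unit_id, g in df.groupby("unit_id", sort=True):
        trains.append(
            SpikeTrain(str(unit_id), np.sort(g["time_s"].to_numpy()), duration)
        )
    return trains


def write_spikes(trains, path) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame({"unit_id": t.unit_id, "time_s": t.times}) for t in trains
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["unit_id", "time_s"])
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_speed(path) -> SpeedTrace:
    df = _read_csv(path, ["time_s", "voltage_v", "speed_cms"])
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ParseError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValidationError(f"{path}: sampling is not uniform")
    return SpeedTrace(
        sample_rate=1.0 / dt[0],
        voltage=df["voltage_v"].to_numpy(),
        speed=df["speed_cms"].to_numpy(),
    )


def write_speed(trace: SpeedTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": trace.times,
            "voltage_v": trace.voltage,
            "speed_cms": trace.speed,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_trials(path, baseline_window: float = 0.1) -> ToneTrialTable:
    df = _read_csv(path, ["trial_id", "onset_s", "freq_khz", "level_db", "duration_s"])
    return ToneTrialTable(
        df["onset_s"].to_numpy(),
        df["freq_khz"].to_numpy(),
        df["level_db"].to_numpy(),
        df["duration_s"].to_numpy(),
        baseline_window=baseline_window,
    )


def write_trials(trials: ToneTrialTable, path) -> Path:
    path = Path(path)
    trials.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_segments(path, speed_threshold: float = 2.0) -> BehaviorSegments:
    df = _read_csv(path, ["start_s", "end_s", "label"])
    return BehaviorSegments(
        df["start_s"].to_numpy(),
        df["end_s"].to_numpy(),
        df["label"].to_numpy(dtype=object),
        speed_threshold=speed_threshold,
    )


def write_segments(segments: BehaviorSegments, path) -> Path:
    path = Path(path)
    segments.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_onsets(path) -> np.ndarray:
    df = _read_csv(path, ["onset_s"])
    return df["onset_s"].to_numpy()


def write_onsets(onsets, path) -> Path:
    path = Path(path)
    pd.DataFrame({"onset_s": np.asarray(onsets, float)}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    return path


def read_audio(path) -> AudioTrace:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    else:
        samples = data.astype(float)
    return AudioTrace(sample_rate=float(rate), samples=samples)


def write_audio(audio: AudioTrace, path, normalize: bool = True) -> Path:
    """Write 16-bit PCM WAV; by default rescales to 90% full scale."""
    path = Path(path)
    x = audio.samples
    peak = np.max(np.abs(x)) if x.size else 0.0
    if normalize and peak > 0:
        x = x / peak * 0.9
    wavfile.write(path, int(round(audio.sample_rate)), (x * 32767).astype(np.int16))
    return path


def read_config(path) -> dict:
    """Flat key→value run configuration (YAML mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a flat key-value mapping")
    return cfg


def write_config(cfg: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
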