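"""Core data types shared by all analysis stages.

Conventions
-----------
* Time is in seconds (float); all intervals are half-open ``[start, end)``
  so a spike or sample on a boundary is counted exactly once.
* Frequencies are stored in kHz and converted to log2(kHz) only inside
  tuning computations.
* Treadmill speed is in cm/s; the rotary-encoder output voltage lives in
  ``[0, 2.5]`` V and wraps around once per encoder cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "InsufficientDataError",
    "SpikeTrain",
    "SpeedTrace",
    "ToneTrialTable",
    "AudioTrace",
    "BehaviorSegments",
    "qc_refractory",
]


class ValidationError(ValueError):
    """Raised when input data violate a documented invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; names the offending line."""


class InsufficientDataError(RuntimeError):
    """Raised when a unit lacks the data required by an analysis stage."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one unit over a recording of known duration."""

    unit_id: str
    times: np.ndarray  # seconds, nondecreasing
    duration: float  # seconds

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValidationError(f"{self.unit_id}: spike times must be 1-D")
        if self.duration <= 0:
            raise ValidationError(f"{self.unit_id}: duration must be positive")
        if times.size:
            if not np.all(np.diff(times) >= 0):
                raise ValidationError(f"{self.unit_id}: spike times not sorted")
            if times[0] < 0 or times[-1] > self.duration:
                raise ValidationError(
                    f"{self.unit_id}: spike times outside [0, duration]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def mean_rate(self) -> float:
        return self.n_spikes / self.duration

    def count_in(self, start: float, end: float) -> int:
        """Spike count in the half-open window ``[start, end)``."""
        lo, hi = np.searchsorted(self.times, [start, end], side="left")
        return int(hi - lo)


@dataclass(frozen=True)
class SpeedTrace:
    """Uniformly sampled treadmill sensor voltage and calibrated speed."""

    sample_rate: float  # Hz
    voltage: np.ndarray  # volts, in [0, full_range]
    speed: np.ndarray  # cm/s, nonnegative
    full_range: float = 2.5  # volts

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage, dtype=float)
        s = np.asarray(self.speed, dtype=float)
        object.__setattr__(self, "voltage", v)
        object.__setattr__(self, "speed", s)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if v.shape != s.shape or v.ndim != 1:
            raise ValidationError("voltage and speed must be equal-length 1-D")
        if s.size and s.min() < 0:
            raise ValidationError("speed must be nonnegative")
        if v.size and (v.min() < -1e-9 or v.max() > self.full_range + 1e-9):
            raise ValidationError("voltage outside sensor range")

    @property
    def n_samples(self) -> int:
        return int(self.speed.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class ToneTrialTable:
    """Tone (or noise-burst) trials: onset, frequency, level, duration.

    ``baseline_window`` is the pre-onset window (s) used for spontaneous
    rate estimation — 0.1 or 0.2 s depending on the stimulus schedule.
    """

    onset_s: np.ndarray
    freq_khz: np.ndarray
    level_db: np.ndarray
    duration_s: np.ndarray
    baseline_window: float = 0.1

    def __post_init__(self) -> None:
        for name in ("onset_s", "freq_khz", "level_db", "duration_s"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = self.onset_s.size
        if any(
            getattr(self, f).size != n
            for f in ("freq_khz", "level_db", "duration_s")
        ):
            raise ValidationError("trial columns must have equal length")
        if n > 1 and not np.all(np.diff(self.onset_s) > 0):
            raise ValidationError("trial onsets must be strictly increasing")
        if self.baseline_window <= 0:
            raise ValidationError("baseline_window must be positive")

    @property
    def n_trials(self) -> int:
        return int(self.onset_s.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": np.arange(self.n_trials),
                "onset_s": self.onset_s,
                "freq_khz": self.freq_khz,
                "level_db": self.level_db,
                "duration_s": self.duration_s,
            }
        )

    def subset(self, mask: np.ndarray) -> "ToneTrialTable":
        return ToneTrialTable(
            self.onset_s[mask],
            self.freq_khz[mask],
            self.level_db[mask],
            self.duration_s[mask],
            self.baseline_window,
        )


@dataclass(frozen=True)
class AudioTrace:
    """Pressure waveform in arbitrary linear units."""

    sample_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", x)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if x.size and not np.all(np.isfinite(x)):
            raise ValidationError("audio samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


STATIONARY = "stationary"
WALKING = "walking"


@dataclass(frozen=True)
class BehaviorSegments:
    """Alternating stationary/walking intervals covering a recording."""

    starts: np.ndarray
    ends: np.ndarray
    labels: np.ndarray  # "stationary" | "walking"
    speed_threshold: float = 2.0  # cm/s

    def __post_init__(self) -> None:
        s = np.asarray(self.starts, float)
        e = np.asarray(self.ends, float)
        lab = np.asarray(self.labels, object)
        object.__setattr__(self, "starts", s)
        object.__setattr__(self, "ends", e)
        object.__setattr__(self, "labels", lab)
        if not (s.size == e.size == lab.size):
            raise ValidationError("segment columns must have equal length")
        if s.size:
            if np.any(e <= s):
                raise ValidationError("segment ends must exceed starts")
            if np.any(s[1:] < e[:-1] - 1e-9):
                raise ValidationError("segments must not overlap")

    @property
    def n_segments(self) -> int:
        return int(self.starts.size)

    def intervals(self, label: str) -> np.ndarray:
        """(n, 2) array of [start, end) intervals carrying ``label``."""
        m = self.labels == label
        return np.column_stack([self.starts[m], self.ends[m]])

    def total_duration(self, label: str) -> float:
        iv = self.intervals(label)
        return float((iv[:, 1] - iv[:, 0]).sum()) if iv.size else 0.0

    def label_at(self, t: float) -> str | None:
        """Label of the interval containing time ``t`` (half-open)."""
        i = np.searchsorted(self.ends, t, side="right")
        if i < self.n_segments and self.starts[i] <= t < self.ends[i]:
            return str(self.labels[i])
        return None

    def contains(self, start: float, end: float, label: str | None = None) -> bool:
        """True if ``[start, end)`` lies wholly inside one labeled interval."""
        i = np.searchsorted(self.ends, start, side="right")
        if i >= self.n_segments:
            return False
        ok = self.starts[i] <= start and end <= self.ends[i] + 1e-9
        if not ok:
            return False
        return label is None or self.labels[i] == label

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start_s": self.starts, "end_s": self.ends, "label": self.labels}
        )


def qc_refractory(train: SpikeTrain, refractory: float = 0.0007) -> float:
    """Fraction of inter-spike intervals shorter than the refractory period.

    Single units are required to have a violation fraction ≤ 0.005 at a
    0.7 ms refractory period; trains with fewer than two spikes have no
    ISIs and return 0.
    """
    if train.n_spikes < 2:
        return 0.0
    isi = np.diff(train.times)
    return float(np.mean(isi < refractory))
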