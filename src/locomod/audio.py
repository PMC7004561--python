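"""Walking-sound analysis: bandpass filtering, envelope-threshold event
detection, RMS measures, sound-level estimation against a playback
ladder, and the playback-vs-locomotion comparison.

dB values here are relative ladder labels, not absolute SPL calibrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from scipy.ndimage import uniform_filter1d

from .core import AudioTrace, InsufficientDataError, ValidationError

__all__ = [
    "bandpass",
    "envelope",
    "AudioEvents",
    "detect_audio_events",
    "rms",
    "event_rms",
    "level_match",
    "playback_vs_locomotion",
]


def bandpass(
    audio: AudioTrace, low: float = 1000.0, high: float = 25000.0, order: int = 4
) -> AudioTrace:
    """Zero-phase 1–25 kHz Butterworth bandpass (forward–backward), so
    event timing is not skewed by filter delay."""
    if audio.sample_rate <= 2 * high:
        raise ValidationError("sample rate too low for the requested band")
    sos = signal.butter(
        order, [low, high], btype="bandpass", fs=audio.sample_rate, output="sos"
    )
    return AudioTrace(audio.sample_rate, signal.sosfiltfilt(sos, audio.samples))


def envelope(audio: AudioTrace, smooth: float = 0.002) -> np.ndarray:
    """Rectified waveform smoothed with a rectangular window (2 ms)."""
    n = max(1, int(round(smooth * audio.sample_rate)))
    return uniform_filter1d(np.abs(audio.samples), n)


@dataclass(frozen=True)
class AudioEvents:
    """Event intervals defined on a reference envelope at a fractional
    threshold of its peak."""

    intervals: np.ndarray  # (n, 2) start/end seconds, non-overlapping
    threshold: float  # envelope units
    sample_rate: float

    @property
    def n_events(self) -> int:
        return int(self.intervals.shape[0]) if self.intervals.size else 0

    @property
    def onsets(self) -> np.ndarray:
        return self.intervals[:, 0] if self.intervals.size else np.array([])

    def mask(self, n_samples: int) -> np.ndarray:
        m = np.zeros(n_samples, bool)
        for s, e in self.intervals:
            m[int(round(s * self.sample_rate)) : int(round(e * self.sample_rate))] = True
        return m


def detect_audio_events(
    reference: AudioTrace,
    smooth: float = 0.002,
    threshold_frac: float = 0.04,
    min_gap: float = 0.002,
) -> AudioEvents:
    """Events where the reference envelope reaches ``threshold_frac`` of
    its peak (4% of the 40 dB playback by convention); the same events
    are then reused to compare the walking-sound and playback traces.

    Intervals closer than ``min_gap`` are merged. A silent reference
    (zero peak) yields no events.
    """
    env = envelope(reference, smooth)
    peak = float(env.max(initial=0.0))
    thr = threshold_frac * peak
    if peak <= 0:
        return AudioEvents(np.empty((0, 2)), thr, reference.sample_rate)
    above = env >= thr
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.insert(starts, 0, 0)
    if above[-1]:
        ends = np.append(ends, above.size)
    fs = reference.sample_rate
    merged = []
    for s, e in zip(starts / fs, ends / fs):
        if merged and s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return AudioEvents(np.asarray(merged, float).reshape(-1, 2), thr, fs)


def rms(x) -> float:
    """Root mean square of a waveform (invariant to sign flip and
    time reversal)."""
    x = np.asarray(x if not isinstance(x, AudioTrace) else x.samples, float)
    if x.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(x**2)))


def event_rms(audio: AudioTrace, events: AudioEvents) -> float:
    """RMS restricted to the event windows (falls back to whole-trace RMS
    when there are no events)."""
    m = events.mask(audio.samples.size)
    if not m.any():
        return rms(audio)
    return rms(audio.samples[m])


def level_match(
    walk_audio: AudioTrace,
    ladder: dict,
    events: AudioEvents | None = None,
    scope: str = "events",
) -> float:
    """Estimated walking-sound level: the ladder rung (dB label) whose
    RMS is nearest the walking-sound RMS.

    ``scope='events'`` compares event-window RMS (the ladder traces share
    the event definition); ``scope='whole'`` compares whole-trace RMS.
    """
    if not ladder:
        raise ValidationError("empty playback ladder")
    if scope == "events" and events is not None:
        measure = lambda a: event_rms(a, events)  # noqa: E731
    elif scope in ("whole", "events"):
        measure = rms
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    target = measure(walk_audio)
    levels = sorted(ladder)
    dists = [abs(measure(ladder[lev]) - target) for lev in levels]
    return float(levels[int(np.argmin(dists))])


def playback_vs_locomotion(
    playback_change, locomotion_change, exclude=None
):
    """Pearson correlation between playback-evoked and locomotion-induced
    rate changes across units, with a t-test of r ≠ 0.

    ``exclude`` masks out units whose baseline playback periods
    themselves evoke responses. Playback responses must come from
    stationary trials only (the caller's responsibility).
    """
    a = np.asarray(playback_change, float)
    b = np.asarray(locomotion_change, float)
    if a.size != b.size:
        raise ValidationError("vectors must have equal length")
    if exclude is not None:
        keep = ~np.asarray(exclude, bool)
        a, b = a[keep], b[keep]
    if a.size < 3:
        raise InsufficientDataError("need at least 3 units for a correlation")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
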