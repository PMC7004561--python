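"""Treadmill signal processing: speed smoothing, stationary/walking
segmentation, locomotion-onset detection, and spontaneous-rate segments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    STATIONARY,
    WALKING,
    BehaviorSegments,
    SpeedTrace,
    SpikeTrain,
    ToneTrialTable,
    ValidationError,
)

__all__ = [
    "smooth_speed",
    "hanning_smooth",
    "segment_behavior",
    "detect_locomotion_onsets",
    "extract_spontaneous_segments",
]


def hanning_smooth(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Convolve with a unit-sum hanning window, reflect-padded at edges."""
    n = int(window_samples)
    if n < 2:
        raise ValidationError("smoothing window must span at least 2 samples")
    if n > x.size:
        raise ValidationError("smoothing window longer than the trace")
    if n % 2 == 0:
        n += 1  # odd length keeps the output aligned with the input
    kernel = np.hanning(n + 2)[1:-1]  # drop the zero end taps
    kernel /= kernel.sum()
    pad = n // 2
    xp = np.pad(x, pad, mode="reflect")
    return np.convolve(xp, kernel, mode="valid")


def smooth_speed(
    trace: SpeedTrace, window: float = 0.2, kernel: str = "hanning"
) -> SpeedTrace:
    """200 ms hanning smoothing of the speed channel (voltage untouched)."""
    if kernel != "hanning":
        raise ValidationError(f"unknown kernel {kernel!r}")
    n = int(round(window * trace.sample_rate))
    smoothed = hanning_smooth(trace.speed, n)
    return SpeedTrace(
        trace.sample_rate,
        trace.voltage,
        np.maximum(smoothed, 0.0),
        trace.full_range,
    )


def segment_behavior(
    smoothed: SpeedTrace, threshold: float = 2.0, min_duration: float = 0.0
) -> BehaviorSegments:
    """Label walking where smoothed speed > threshold (cm/s).

    ``min_duration`` > 0 merges shorter interior intervals into their
    neighbours (off by default: brief movement blips are retained).
    """
    walking = smoothed.speed > threshold
    n = walking.size
    if n == 0:
        return BehaviorSegments(
            np.array([]), np.array([]), np.array([], object), threshold
        )
    change = np.flatnonzero(np.diff(walking.astype(int))) + 1
    bounds = np.concatenate([[0], change, [n]])
    starts = bounds[:-1] / smoothed.sample_rate
    ends = bounds[1:] / smoothed.sample_rate
    labels = np.array(
        [WALKING if walking[i] else STATIONARY for i in bounds[:-1]], object
    )
    if min_duration > 0:
        starts, ends, labels = _merge_short(starts, ends, labels, min_duration)
    return BehaviorSegments(starts, ends, labels, threshold)


def _merge_short(starts, ends, labels, min_duration):
    """Flip interior intervals shorter than min_duration, then coalesce."""
    keep = list(zip(starts, ends, labels))
    out = []
    for i, (s, e, lab) in enumerate(keep):
        if 0 < i < len(keep) - 1 and (e - s) < min_duration:
            lab = out[-1][2]  # absorb into the preceding interval's label
        if out and out[-1][2] == lab:
            out[-1] = (out[-1][0], e, lab)
        else:
            out.append((s, e, lab))
    s, e, lab = zip(*out)
    return np.array(s), np.array(e), np.array(lab, object)


def _unwrapped_travel(voltage: np.ndarray, full_range: float) -> np.ndarray:
    """Cumulative voltage change with encoder wraparound removed."""
    d = np.diff(voltage, prepend=voltage[:1])
    d = np.where(d < -full_range / 2, d + full_range, d)
    d = np.where(d > full_range / 2, d - full_range, d)
    return np.cumsum(d)


def detect_locomotion_onsets(
    trace: SpeedTrace,
    segments: BehaviorSegments,
    fraction: float = 0.02,
    full_range: float = 2.5,
    min_pre_stationary: float = 1.0,
) -> np.ndarray:
    """Locomotion onsets: first time accumulated travel within an eligible
    walking bout reaches 2% of the 2.5 V sensor range (<1 mm of travel).

    A bout is eligible (a "clear onset") only when preceded by at least
    ``min_pre_stationary`` seconds of stationary behaviour. Bouts whose
    travel never reaches the criterion contribute no onset.
    """
    travel = _unwrapped_travel(trace.voltage, full_range)
    fs = trace.sample_rate
    onsets = []
    for i in range(segments.n_segments):
        if segments.labels[i] != WALKING:
            continue
        start = segments.starts[i]
        if i == 0 or segments.labels[i - 1] != STATIONARY:
            continue
        if (segments.ends[i - 1] - segments.starts[i - 1]) < min_pre_stationary:
            continue
        i0 = int(round(start * fs))
        i1 = int(round(segments.ends[i] * fs))
        seg = travel[i0:i1] - travel[i0]
        hits = np.flatnonzero(seg >= fraction * full_range)
        if hits.size:
            onsets.append((i0 + hits[0]) / fs)
    return np.asarray(onsets)


def extract_spontaneous_segments(
    train: SpikeTrain,
    segments: BehaviorSegments,
    mode: str = "fixed_chunks",
    chunk: float = 1.0,
    trials: ToneTrialTable | None = None,
) -> pd.DataFrame:
    """Per-segment firing rates labeled stationary/walking.

    ``fixed_chunks`` tiles each behavioural interval with non-overlapping
    ``chunk``-second windows; ``baseline_windows`` uses the pre-stimulus
    baseline of each trial. Either way a window is kept only if it lies
    wholly inside one labeled interval, and rate = spikes / window length.
    """
    rows = []
    if mode == "fixed_chunks":
        for i in range(segments.n_segments):
            s, e, lab = segments.starts[i], segments.ends[i], segments.labels[i]
            k = int(np.floor((e - s) / chunk + 1e-9))
            for j in range(k):
                a = s + j * chunk
                rows.append((a, a + chunk, lab, train.count_in(a, a + chunk) / chunk))
    elif mode == "baseline_windows":
        if trials is None:
            raise ValidationError("baseline_windows mode requires trials")
        w = trials.baseline_window
        for on in trials.onset_s:
            a, b = on - w, on
            lab = segments.label_at(a)
            if lab is not None and segments.contains(a, b, lab):
                rows.append((a, b, lab, train.count_in(a, b) / w))
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows, columns=["start_s", "end_s", "label", "rate_hz"])
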