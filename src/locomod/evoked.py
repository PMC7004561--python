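"""Tone-evoked activity: PSTHs, response windows, evoked rates and their
locomotion modulation, temporal response types, and multi-unit
rate-level / hearing-threshold analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .core import (
    STATIONARY,
    WALKING,
    BehaviorSegments,
    InsufficientDataError,
    SpikeTrain,
    ToneTrialTable,
    ValidationError,
)

__all__ = [
    "PSTH",
    "build_psth",
    "define_response_window",
    "assign_trial_conditions",
    "EvokedRate",
    "evoked_rate",
    "percent_change",
    "percent_change_unit",
    "classify_response_type",
    "detect_multiunit_spikes",
    "RateLevelCurve",
    "rate_level_curve",
    "EvokedUnitResult",
    "analyze_evoked_unit",
]

ONSET = "onset"
SUSTAINED = "sustained"
SUPPRESSED = "suppressed"

FIXED_WINDOW = (0.005, 0.020)  # 15 ms window starting 5 ms after onset


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged Gaussian-smoothed peristimulus time histogram."""

    time: np.ndarray  # bin centres, s relative to stimulus onset
    rate: np.ndarray  # Hz
    n_trials: int
    condition: str | None = None
    bin_width: float = 0.001
    sigma: float = 0.002

    def peak(self, t_min: float | None = None, t_max: float | None = None):
        """(time, rate) of the maximum within [t_min, t_max]."""
        m = np.ones(self.time.size, bool)
        if t_min is not None:
            m &= self.time >= t_min
        if t_max is not None:
            m &= self.time <= t_max
        idx = np.flatnonzero(m)
        i = idx[np.argmax(self.rate[idx])]
        return float(self.time[i]), float(self.rate[i])

    def mean_rate(self, t_min: float, t_max: float) -> float:
        m = (self.time >= t_min) & (self.time < t_max)
        return float(self.rate[m].mean()) if m.any() else float("nan")


def build_psth(
    train: SpikeTrain,
    trial_onsets,
    t_range=(-0.05, 0.1),
    bin_width: float = 0.001,
    sigma: float = 0.002,
    condition: str | None = None,
) -> PSTH:
    """Bin spikes relative to stimulus onset (1 ms bins), average across
    trials, and smooth with a unit-area Gaussian of SD 2 ms.

    The histogram is built on a padded range and cropped after smoothing
    so edge bins are not distorted by the kernel.
    """
    onsets = np.asarray(trial_onsets, float)
    if onsets.size == 0:
        raise InsufficientDataError("PSTH needs at least one trial")
    pad = 6 * sigma
    lo, hi = t_range[0] - pad, t_range[1] + pad
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + np.arange(n_bins + 1) * bin_width
    rel = (train.times[None, :] - onsets[:, None]).ravel()
    counts, _ = np.histogram(rel, bins=edges)
    rate = counts / (onsets.size * bin_width)
    rate = gaussian_filter1d(rate, sigma / bin_width, truncate=6.0)
    centers = edges[:-1] + bin_width / 2
    keep = (centers >= t_range[0]) & (centers < t_range[1])
    return PSTH(centers[keep], rate[keep], onsets.size, condition, bin_width, sigma)


def define_response_window(
    psth: PSTH,
    pre: float = 0.005,
    post: float = 0.007,
    search=(0.0, None),
    mode: str = "peak",
):
    """Response window: [peak − 5 ms, peak + 7 ms] around the PSTH peak at
    the best frequency; ``mode='fixed15'`` returns the fixed 5–20 ms
    window irrespective of the peak. ``None`` when the PSTH is flat (no
    excitatory deflection to anchor a peak on).
    """
    if mode == "fixed15":
        return FIXED_WINDOW
    if mode != "peak":
        raise ValidationError(f"unknown window mode {mode!r}")
    t_peak, r_peak = psth.peak(search[0], search[1])
    if r_peak <= 0 or np.allclose(psth.rate, psth.rate[0]):
        return None
    return (t_peak - pre, t_peak + post)


def assign_trial_conditions(
    trials: ToneTrialTable, segments: BehaviorSegments
) -> np.ndarray:
    """Per-trial behavioural label, or None when the baseline+stimulus
    epoch does not lie wholly inside one labeled interval."""
    out = np.full(trials.n_trials, None, dtype=object)
    for i in range(trials.n_trials):
        a = trials.onset_s[i] - trials.baseline_window
        b = trials.onset_s[i] + trials.duration_s[i]
        lab = segments.label_at(a)
        if lab is not None and segments.contains(a, b, lab):
            out[i] = lab
    return out


@dataclass(frozen=True)
class EvokedRate:
    """Evoked rate of one (frequency, condition) cell."""

    r_evoked: float  # window rate − baseline rate, Hz
    spontaneous: float  # baseline rate, Hz
    p_value: float
    significant: bool  # paired test p < α and excitatory
    n_trials: int


def evoked_rate(
    train: SpikeTrain,
    trial_onsets,
    window,
    baseline_window: float,
    alpha: float = 0.05,
) -> EvokedRate:
    """Mean response-window rate minus the mean pre-stimulus baseline rate.

    Significance: two-sided paired t-test of per-trial window vs baseline
    rates at α, counted only in the excitatory direction (window >
    baseline); constant differences give p = 1.
    """
    onsets = np.asarray(trial_onsets, float)
    w0, w1 = window
    wlen = w1 - w0
    win = np.array([train.count_in(on + w0, on + w1) / wlen for on in onsets])
    base = np.array(
        [train.count_in(on - baseline_window, on) / baseline_window for on in onsets]
    )
    diff = win - base
    if onsets.size > 1 and np.std(diff) > 0:
        _, p = stats.ttest_rel(win, base)
        p = float(p)
    else:
        p = 1.0
    r_ev = float(diff.mean())
    return EvokedRate(
        r_evoked=r_ev,
        spontaneous=float(base.mean()),
        p_value=p,
        significant=bool(p < alpha and r_ev > 0),
        n_trials=onsets.size,
    )


def percent_change(r_stat: float, r_walk: float) -> float:
    """100·(r_evoked(walking) − r_evoked(stationary)) / r_evoked(stationary)."""
    return float(100.0 * (r_walk - r_stat) / r_stat)


def percent_change_unit(
    r_stat, r_walk, mode: str = "ratio_of_sums"
) -> float:
    """Unit-level percent change over the responsive frequencies.

    ``ratio_of_sums`` (default) applies the percent-change formula to the
    frequency-summed evoked rates, which keeps the result bounded on the
    population scale; ``sum_of_percent`` literally sums the per-frequency
    percentages.
    """
    a = np.asarray(r_stat, float)
    b = np.asarray(r_walk, float)
    if a.size == 0:
        raise InsufficientDataError("no responsive frequencies")
    if mode == "ratio_of_sums":
        return percent_change(float(a.sum()), float(b.sum()))
    if mode == "sum_of_percent":
        return float(np.sum(100.0 * (b - a) / a))
    raise ValidationError(f"unknown mode {mode!r}")


def classify_response_type(
    psth: PSTH,
    stim_duration: float,
    baseline_rate: float,
    stim_rates=None,
    baseline_rates=None,
    alpha: float = 0.05,
    onset_fraction: float = 0.25,
) -> str:
    """Temporal response type from the stationary PSTH.

    Suppressed: stimulus-period rate significantly below baseline (paired
    t-test on per-trial rates when supplied, otherwise a < 50%-of-baseline
    heuristic). Otherwise, onset if the mean rate over the last half of
    the stimulus has fallen below baseline + 25% of (peak − baseline),
    sustained if it stays at or above that bound.
    """
    stim_mean = psth.mean_rate(0.0, stim_duration + 0.005)
    if stim_rates is not None and baseline_rates is not None:
        s = np.asarray(stim_rates, float)
        b = np.asarray(baseline_rates, float)
        if s.size > 1 and np.std(s - b) > 0:
            _, p = stats.ttest_rel(s, b)
            if p < alpha and s.mean() < b.mean():
                return SUPPRESSED
    elif stim_mean < 0.5 * baseline_rate:
        return SUPPRESSED
    _, peak = psth.peak(0.0, stim_duration + 0.005)
    last_half = psth.mean_rate(stim_duration / 2, stim_duration + 0.005)
    bound = baseline_rate + onset_fraction * (peak - baseline_rate)
    return ONSET if last_half < bound else SUSTAINED


def detect_multiunit_spikes(
    voltage: np.ndarray,
    sample_rate: float,
    baseline_windows=None,
    k: float = 3.0,
    dead_time: float = 0.001,
) -> np.ndarray:
    """Threshold crossings of |v| at k× the baseline-noise SD with a 1 ms
    dead time; returns event times in seconds.

    The noise SD is estimated from the given pre-stimulus baseline
    windows, or from the whole trace when none are given.
    """
    v = np.asarray(voltage, float)
    if baseline_windows is not None:
        chunks = []
        for s, e in baseline_windows:
            chunks.append(v[int(round(s * sample_rate)) : int(round(e * sample_rate))])
        noise = np.concatenate(chunks) if chunks else v
    else:
        noise = v
    thr = k * float(np.std(noise))
    above = np.abs(v) >= thr
    crossings = np.flatnonzero(above & ~np.roll(above, 1))
    if crossings.size and above[0]:
        crossings = crossings[crossings != 0]
        crossings = np.insert(crossings, 0, 0)
    if crossings.size == 0:
        return np.array([])
    dead = int(round(dead_time * sample_rate))
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= dead:
            kept.append(c)
    return np.asarray(kept) / sample_rate


@dataclass(frozen=True)
class RateLevelCurve:
    """Peak evoked rate vs sound level, plus the hearing threshold."""

    levels: np.ndarray  # dB SPL, sorted
    peak_rate: np.ndarray  # peak evoked rate per level, Hz
    significant: np.ndarray  # excitatory paired-test flag per level
    hearing_threshold: float | None  # dB SPL; None when no level responds


def rate_level_curve(
    event_times,
    trials: ToneTrialTable,
    alpha: float = 0.05,
    min_peak_fraction: float = 0.2,
    sigma: float = 0.002,
) -> RateLevelCurve:
    """Rate-level function of a multi-unit site.

    Per level: peak of the 2 ms-smoothed PSTH minus the baseline rate,
    and a paired t-test of stimulus-window vs baseline per-trial rates.
    The hearing threshold is the lowest level with a significant
    excitatory response whose peak evoked rate reaches at least
    ``min_peak_fraction`` of the site's maximum — the effect-size floor
    guards against isolated false-positive levels.
    """
    events = np.asarray(event_times, float)
    duration = float(trials.onset_s[-1] + trials.duration_s[-1] + 1.0)
    train = SpikeTrain("mua", events, max(duration, events.max() + 1 if events.size else 1.0))
    levels = np.unique(trials.level_db)
    bw = trials.baseline_window
    peak_rates, sigs = [], []
    for lev in levels:
        m = trials.level_db == lev
        onsets = trials.onset_s[m]
        dur = float(trials.duration_s[m][0])
        psth = build_psth(train, onsets, t_range=(-bw, dur + 0.02), sigma=sigma)
        base = np.array([train.count_in(on - bw, on) / bw for on in onsets])
        win = np.array(
            [train.count_in(on, on + dur + 0.01) / (dur + 0.01) for on in onsets]
        )
        diff = win - base
        if onsets.size > 1 and np.std(diff) > 0:
            _, p = stats.ttest_rel(win, base)
        else:
            p = 1.0
        _, peak = psth.peak(0.0, dur + 0.01)
        peak_rates.append(peak - base.mean())
        sigs.append(bool(p < alpha and diff.mean() > 0))
    peak_rates = np.asarray(peak_rates)
    sigs = np.asarray(sigs)
    threshold = None
    max_peak = peak_rates.max() if peak_rates.size else 0.0
    for lev, pk, sig in zip(levels, peak_rates, sigs):
        if sig and pk >= min_peak_fraction * max_peak and pk > 0:
            threshold = float(lev)
            break
    return RateLevelCurve(levels, peak_rates, sigs, threshold)


@dataclass(frozen=True)
class EvokedUnitResult:
    """Per-unit evoked analysis: one row per (frequency, condition)."""

    unit_id: str
    best_frequency: float  # kHz, from stationary PSTH peaks
    response_window: tuple
    response_type: str
    table: pd.DataFrame  # freq_khz, condition, n_trials, r_evoked_hz,
    # spont_hz, p_value, significant
    pct_change_by_freq: pd.DataFrame  # freq_khz, pct_change, reliable
    pct_change_unit: float | None


def analyze_evoked_unit(
    train: SpikeTrain,
    trials: ToneTrialTable,
    segments: BehaviorSegments,
    min_trials: int = 5,
    window_mode: str = "peak",
    alpha: float = 0.05,
    pct_floor: float = 1.0,
    pct_mode: str = "ratio_of_sums",
) -> EvokedUnitResult:
    """Full tone-evoked analysis of one unit.

    Trials are assigned to stationary/walking only when the whole
    baseline+stimulus epoch sits inside one behavioural interval; a
    frequency enters a condition only with ≥ ``min_trials`` trials. The
    response window is fixed per unit from the stationary PSTH at the
    best frequency and reused for every stimulus. Per-frequency percent
    change requires a stationary evoked rate above ``pct_floor`` (Hz);
    the unit-level value is the ratio-of-sums over responsive
    frequencies present in both conditions.
    """
    cond = assign_trial_conditions(trials, segments)
    freqs = np.unique(trials.freq_khz)
    stim_dur = float(trials.duration_s[0])
    bw = trials.baseline_window

    # best frequency from stationary PSTH peak heights; ties -> lower freq
    stat_psths = {}
    peaks = np.full(freqs.size, -np.inf)
    for i, f in enumerate(freqs):
        m = (trials.freq_khz == f) & (cond == STATIONARY)
        if m.sum() < min_trials:
            continue
        p = build_psth(
            train, trials.onset_s[m], t_range=(-bw, stim_dur + 0.05),
            condition=STATIONARY,
        )
        stat_psths[f] = p
        _, peaks[i] = p.peak(0.0, stim_dur + 0.01)
    if not np.isfinite(peaks).any() or not stat_psths:
        raise InsufficientDataError("no frequency with enough stationary trials")
    bf = float(freqs[int(np.argmax(peaks))])  # argmax takes the first (lower) tie

    window = define_response_window(stat_psths[bf], mode=window_mode)
    if window is None:
        raise InsufficientDataError("flat PSTH: no excitatory response")

    rows = []
    for f in freqs:
        for c in (STATIONARY, WALKING):
            m = (trials.freq_khz == f) & (cond == c)
            if m.sum() < min_trials:
                continue
            er = evoked_rate(train, trials.onset_s[m], window, bw, alpha=alpha)
            rows.append(
                {
                    "freq_khz": f,
                    "condition": c,
                    "n_trials": er.n_trials,
                    "r_evoked_hz": er.r_evoked,
                    "spont_hz": er.spontaneous,
                    "p_value": er.p_value,
                    "significant": er.significant,
                }
            )
    table = pd.DataFrame(rows)

    # per-frequency percent change at responsive (significant stationary) tones
    pct_rows = []
    stat_ok, walk_ok = [], []
    for f in freqs:
        r_s = table[(table.freq_khz == f) & (table.condition == STATIONARY)]
        r_w = table[(table.freq_khz == f) & (table.condition == WALKING)]
        if r_s.empty or r_w.empty or not bool(r_s.significant.iloc[0]):
            continue
        rs, rw = float(r_s.r_evoked_hz.iloc[0]), float(r_w.r_evoked_hz.iloc[0])
        reliable = abs(rs) >= pct_floor
        pct_rows.append(
            {
                "freq_khz": f,
                "pct_change": percent_change(rs, rw) if reliable else np.nan,
                "reliable": reliable,
            }
        )
        if reliable:
            stat_ok.append(rs)
            walk_ok.append(rw)
    pct_by_freq = pd.DataFrame(pct_rows)
    pct_unit = (
        percent_change_unit(stat_ok, walk_ok, mode=pct_mode) if stat_ok else None
    )

    # response type from the stationary best-frequency trials
    m_bf = (trials.freq_khz == bf) & (cond == STATIONARY)
    on_bf = trials.onset_s[m_bf]
    stim_rates = [train.count_in(o, o + stim_dur) / stim_dur for o in on_bf]
    base_rates = [train.count_in(o - bw, o) / bw for o in on_bf]
    rtype = classify_response_type(
        stat_psths[bf],
        stim_dur,
        float(np.mean(base_rates)),
        stim_rates=stim_rates,
        baseline_rates=base_rates,
        alpha=alpha,
    )

    return EvokedUnitResult(
        unit_id=train.unit_id,
        best_frequency=bf,
        response_window=window,
        response_type=rtype,
        table=table,
        pct_change_by_freq=pct_by_freq,
        pct_change_unit=pct_unit,
    )
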