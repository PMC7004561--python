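"""Synthetic treadmill sessions with the statistical structure the
analysis assumes.

The generator emulates head-fixed recordings on a passive treadmill:
alternating stationary/walking bouts, spontaneous rates coupled to running
speed (positive or negative gain) with the rate drive *leading* movement,
tone responses with Gaussian-in-log-frequency tuning and onset/sustained/
suppressed temporal profiles, locomotion attenuation that hits weak
responses harder than strong ones, multi-unit rate-level streams with a
configurable hearing threshold, and footstep-like walking audio.

All spike trains are inhomogeneous Poisson processes sampled by thinning
against an explicit rate upper bound, so empirical rates are directly
checkable against the specified intensity function.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import AudioTrace, SpeedTrace, SpikeTrain, ToneTrialTable, ValidationError

__all__ = [
    "SimConfig",
    "ToneSession",
    "RateLevelSession",
    "simulate_speed_trace",
    "simulate_spontaneous_unit",
    "simulate_tone_session",
    "simulate_ratelevel_unit",
    "simulate_walking_audio",
    "make_playback_ladder",
    "gaussian_tuning",
    "attenuate",
]

# Encoder calibration: one 2.5 V cycle corresponds to 4.5 cm of belt travel,
# so 2% of the range is 0.9 mm — "<1 mm of travel".
VOLTS_PER_CM = 2.5 / 4.5

_ONSET_PROFILE = (0.005, 0.020)  # evoked-rate boxcar for onset-type units (s)
_RESPONSE_LATENCY = 0.005  # s from stimulus onset to evoked firing
_SUPPRESSION_FACTOR = 0.2  # suppressed type: rate × 0.2 during the stimulus


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated unit/session.

    Defaults describe a typical strongly-modulated auditory midbrain unit:
    spontaneous rate ``r0`` of 20 Hz, rate–speed gain of 1 Hz per cm/s
    (positive = excited by locomotion), a 100 ms lead of the rate drive
    before movement, Gaussian log-frequency tuning (best frequency 16 kHz,
    SD 0.45 octaves, peak evoked rate 60 Hz), and a locomotion attenuation
    of ``a·(R − s)`` with a = 0.9, s = 5 Hz.
    """

    seed: int = 0
    session_duration: float = 300.0  # s
    bout_rate: float = 6.0  # bouts per minute (mean cycle = 60/bout_rate)
    bout_duration_mean: float = 2.5  # s
    bout_duration_sd: float = 1.0  # s
    peak_speed: float = 15.0  # cm/s
    ramp_time: float = 0.1  # s to reach peak speed (mice accelerate fast)
    speed_sample_rate: float = 100.0  # Hz
    r0: float = 20.0  # baseline rate, Hz
    speed_gain: float = 1.0  # Hz per (cm/s), signed
    modulation_lead: float = 0.1  # s; rate drive precedes movement
    bf_khz: float = 16.0
    sigma_oct: float = 0.45  # tuning SD in octaves (4·SD width = 1.8 oct)
    peak_evoked: float = 60.0  # Hz at best frequency, stationary
    response_type: str = "sustained"  # onset | sustained | suppressed
    atten_gain: float = 0.9  # multiplicative a in (0, 1]
    atten_floor: float = 5.0  # subtractive s, Hz
    deafened_threshold: float = 70.0  # dB SPL hearing threshold

    def __post_init__(self) -> None:
        if self.r0 < 0:
            raise ValidationError("r0 must be nonnegative")
        if self.sigma_oct < 0:
            raise ValidationError("sigma_oct must be nonnegative")
        if not 0 < self.atten_gain <= 1:
            raise ValidationError("atten_gain must be in (0, 1]")
        if self.modulation_lead < 0:
            raise ValidationError("modulation_lead must be nonnegative")
        if self.response_type not in ("onset", "sustained", "suppressed"):
            raise ValidationError(f"unknown response_type {self.response_type!r}")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def gaussian_tuning(freq_khz, cfg: SimConfig, grid=None) -> np.ndarray:
    """Stationary evoked rate R(f) = peak·exp(−(log2 f − log2 BF)²/(2σ²)).

    With ``sigma_oct == 0`` (delta tuning) the response collapses onto the
    grid frequency nearest the best frequency (``grid`` required then).
    """
    f = np.asarray(freq_khz, float)
    if cfg.sigma_oct == 0:
        if grid is None:
            raise ValidationError("delta tuning requires the frequency grid")
        grid = np.asarray(grid, float)
        nearest = grid[np.argmin(np.abs(np.log2(grid) - np.log2(cfg.bf_khz)))]
        return np.where(np.isclose(f, nearest), cfg.peak_evoked, 0.0)
    x = np.log2(f) - np.log2(cfg.bf_khz)
    return cfg.peak_evoked * np.exp(-(x**2) / (2 * cfg.sigma_oct**2))


def attenuate(rate_stationary, cfg: SimConfig) -> np.ndarray:
    """Walking evoked rate: max(0, a·(R − s)).

    The subtractive floor ``s`` removes a fixed number of spikes/s before
    the gain is applied, so weak responses lose a larger *fraction* of
    their rate than strong ones — the generative counterpart of percent
    attenuation being greater for weaker responses.
    """
    r = np.asarray(rate_stationary, float)
    return np.maximum(0.0, cfg.atten_gain * (r - cfg.atten_floor))


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _draw_bouts(cfg: SimConfig, rng, duration: float):
    """Bout (start, duration) pairs from a renewal process.

    The mean cycle length is 60/bout_rate so the long-run bout count is
    ``bout_rate`` per minute; every gap is at least 2 s so each bout is
    preceded by a clean stationary period.
    """
    min_gap = 2.0
    cycle = 60.0 / cfg.bout_rate
    starts, durs = [], []
    gap_mean = max(cycle - cfg.bout_duration_mean - min_gap, 0.1)
    t = min_gap + rng.exponential(gap_mean)
    while True:
        d = rng.normal(cfg.bout_duration_mean, cfg.bout_duration_sd)
        d = float(np.clip(d, 2 * cfg.ramp_time, None))
        if t + d >= duration - 0.5:
            break
        starts.append(t)
        durs.append(d)
        t += d + min_gap + rng.exponential(gap_mean)
    return np.array(starts), np.array(durs)


def _bout_profile(t, start, dur, cfg: SimConfig):
    """Trapezoidal speed profile of one bout evaluated on lattice ``t``."""
    rel = t - start
    up = np.clip(rel / cfg.ramp_time, 0, 1)
    down = np.clip((dur - rel) / cfg.ramp_time, 0, 1)
    inside = (rel >= 0) & (rel <= dur)
    return np.where(inside, cfg.peak_speed * np.minimum(up, down), 0.0)


def simulate_speed_trace(cfg: SimConfig):
    """Treadmill speed/voltage trace plus the true bout onset times.

    Speed is 0 between bouts; each bout ramps linearly to ``peak_speed``
    over ``ramp_time``. Voltage is the accumulated travel mapped through
    the encoder calibration and wrapped at 2.5 V.
    """
    if cfg.session_duration <= 0:
        raise ValidationError("session_duration must be positive")
    rng = _rng(cfg, 1)
    n = int(round(cfg.session_duration * cfg.speed_sample_rate))
    t = np.arange(n) / cfg.speed_sample_rate
    speed = np.zeros(n)
    if cfg.bout_rate > 0:
        starts, durs = _draw_bouts(cfg, rng, cfg.session_duration)
        for s, d in zip(starts, durs):
            speed += _bout_profile(t, s, d, cfg)
    else:
        starts = np.array([])
    travel = np.cumsum(speed) / cfg.speed_sample_rate  # cm
    voltage = (travel * VOLTS_PER_CM) % 2.5
    return SpeedTrace(cfg.speed_sample_rate, voltage, speed), starts


def _bout_intervals(cfg: SimConfig, speed: SpeedTrace, onsets: np.ndarray):
    """True (start, end) of each bout from the noiseless speed trace."""
    moving = speed.speed > 0
    edges = np.diff(moving.astype(int))
    starts = (np.flatnonzero(edges == 1) + 1) / speed.sample_rate
    ends = (np.flatnonzero(edges == -1) + 1) / speed.sample_rate
    if moving.size and moving[0]:
        starts = np.insert(starts, 0, 0.0)
    if moving.size and moving[-1]:
        ends = np.append(ends, speed.duration)
    return np.column_stack([starts, ends])


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------

def _thin(rng, rate: np.ndarray, dt: float) -> np.ndarray:
    """Inhomogeneous Poisson spike times by thinning on lattice ``rate``."""
    rate_max = float(rate.max(initial=0.0))
    duration = rate.size * dt
    if rate_max <= 0:
        return np.array([])
    n = rng.poisson(rate_max * duration)
    cand = rng.uniform(0, duration, n)
    keep = rng.uniform(0, rate_max, n) < rate[
        np.minimum((cand / dt).astype(int), rate.size - 1)
    ]
    return np.sort(cand[keep])


def _lead_shift(x: np.ndarray, lead: float, sample_rate: float) -> np.ndarray:
    """x(t + lead): shift the drive earlier so rate changes precede movement."""
    k = int(round(lead * sample_rate))
    if k == 0:
        return x
    return np.concatenate([x[k:], np.full(min(k, x.size), x[-1] if x.size else 0.0)])


def simulate_spontaneous_unit(
    speed: SpeedTrace,
    onsets: np.ndarray,
    cfg: SimConfig,
    unit_id: str = "sim",
    rate_dt: float = 0.001,
) -> SpikeTrain:
    """Spontaneous spikes with rate(t) = max(0, r0 + g·speed(t + Δ)).

    The speed drive is shifted *earlier* by the modulation lead Δ, so the
    firing-rate change begins Δ before movement onset.
    """
    rng = _rng(cfg, 2)
    drive = _lead_shift(speed.speed, cfg.modulation_lead, speed.sample_rate)
    t_fine = np.arange(int(round(speed.duration / rate_dt))) * rate_dt
    drive_fine = np.interp(t_fine, speed.times, drive)
    rate = np.maximum(0.0, cfg.r0 + cfg.speed_gain * drive_fine)
    times = _thin(rng, rate, rate_dt)
    return SpikeTrain(unit_id, times, speed.duration)


# ---------------------------------------------------------------------------
# tone sessions
# ---------------------------------------------------------------------------

def half_octave_grid() -> np.ndarray:
    """2–64 kHz in half-octave steps (11 frequencies)."""
    return 2.0 * 2 ** (np.arange(11) / 2)


def octave_grid() -> np.ndarray:
    """4–64 kHz in octave steps (5 frequencies)."""
    return 4.0 * 2 ** np.arange(5).astype(float)


@dataclass(frozen=True)
class ToneSession:
    """A simulated tone session plus its generative ground truth."""

    trials: ToneTrialTable
    train: SpikeTrain
    speed: SpeedTrace
    bout_onsets: np.ndarray
    true_condition: np.ndarray  # per trial: stationary | walking | mixed
    truth: dict


def simulate_tone_session(
    cfg: SimConfig,
    freq_grid: np.ndarray | None = None,
    n_repeats: int = 20,
    stim_rate: float = 4.0,
    stim_duration: float = 0.05,
    level_db: float = 70.0,
    baseline_window: float = 0.1,
    unit_id: str = "sim",
) -> ToneSession:
    """Pseudorandom pure-tone trials riding on a walking session.

    Stationary evoked rates follow the Gaussian tuning curve; trials whose
    baseline+stimulus epoch falls inside a walking bout are attenuated by
    ``max(0, a·(R − s))``. Onset-type units fire extra spikes only in the
    first ~15 ms of the stimulus, sustained units throughout, and
    suppressed units drop to 20% of their baseline rate during it.
    """
    if n_repeats < 5:
        raise ValidationError("need at least 5 repeats per frequency")
    rng = _rng(cfg, 3)
    grid = half_octave_grid() if freq_grid is None else np.asarray(freq_grid, float)

    freqs = rng.permuted(np.repeat(grid, n_repeats))
    iti = 1.0 / stim_rate
    onset0 = max(baseline_window, 0.5)
    onsets = onset0 + np.arange(freqs.size) * iti
    duration = float(onsets[-1] + iti + 1.0)

    scfg = cfg.with_(session_duration=duration)
    speed, bout_onsets = simulate_speed_trace(scfg)
    bouts = _bout_intervals(scfg, speed, bout_onsets)

    # true condition of each trial: whole baseline+stimulus epoch inside /
    # outside a bout
    t0 = onsets - baseline_window
    t1 = onsets + stim_duration
    cond = np.full(freqs.size, "mixed", dtype=object)
    in_bout = np.zeros(freqs.size, bool)
    touches = np.zeros(freqs.size, bool)
    for bs, be in bouts:
        in_bout |= (t0 >= bs) & (t1 <= be)
        touches |= (t1 > bs) & (t0 < be)
    cond[in_bout] = "walking"
    cond[~touches] = "stationary"

    r_stat = gaussian_tuning(freqs, cfg, grid)
    r_walk = attenuate(r_stat, cfg)
    amp = np.where(cond == "walking", r_walk, r_stat)  # mixed ≈ stationary

    dt = 0.001
    t_fine = np.arange(int(round(duration / dt))) * dt
    drive = _lead_shift(speed.speed, cfg.modulation_lead, speed.sample_rate)
    rate = np.maximum(0.0, cfg.r0 + cfg.speed_gain * np.interp(t_fine, speed.times, drive))

    if cfg.response_type == "suppressed":
        for on in onsets:
            i0, i1 = int(round(on / dt)), int(round((on + stim_duration) / dt))
            rate[i0:i1] *= _SUPPRESSION_FACTOR
    else:
        if cfg.response_type == "onset":
            prof0, prof1 = _ONSET_PROFILE
        else:  # sustained
            prof0, prof1 = _RESPONSE_LATENCY, stim_duration + _RESPONSE_LATENCY
        for on, a in zip(onsets, amp):
            if a <= 0:
                continue
            i0, i1 = int(round((on + prof0) / dt)), int(round((on + prof1) / dt))
            rate[i0:i1] += a

    train = SpikeTrain(unit_id, _thin(rng, rate, dt), duration)
    trials = ToneTrialTable(
        onsets,
        freqs,
        np.full(freqs.size, level_db),
        np.full(freqs.size, stim_duration),
        baseline_window=baseline_window,
    )
    truth = {
        "bf_khz": float(cfg.bf_khz),
        "response_type": cfg.response_type,
        "freq_grid": grid,
        "r_evoked_stationary": gaussian_tuning(grid, cfg, grid),
        "r_evoked_walking": attenuate(gaussian_tuning(grid, cfg, grid), cfg),
        "modulation_lead": cfg.modulation_lead,
    }
    return ToneSession(trials, train, speed, bout_onsets, cond, truth)


# ---------------------------------------------------------------------------
# multi-unit rate-level streams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateLevelSession:
    trials: ToneTrialTable
    voltage: np.ndarray  # noisy extracellular-like stream
    sample_rate: float
    true_event_times: np.ndarray
    truth: dict


def simulate_ratelevel_unit(
    cfg: SimConfig,
    levels=None,
    n_repeats: int = 50,
    stim_duration: float = 0.05,
    baseline_window: float = 0.1,
    sample_rate: float = 10_000.0,
    background_rate: float = 5.0,
    rate_at_threshold: float = 150.0,
    rate_per_db: float = 5.0,
) -> RateLevelSession:
    """Broadband-noise trials and a voltage-like multi-unit stream.

    Below the configured hearing threshold the stimulus evokes nothing;
    from the threshold level upward the evoked multi-unit rate rises
    linearly with level. Spikes are 6-SD biphasic deflections on unit
    Gaussian noise, so 3×SD threshold crossing recovers them.
    """
    rng = _rng(cfg, 4)
    if levels is None:
        levels = np.arange(20, 100, 10.0)
    levels = np.asarray(levels, float)
    if levels.min() < 20 or levels.max() > 90:
        raise ValidationError("levels must lie within 20–90 dB SPL")

    level_seq = rng.permuted(np.repeat(levels, n_repeats))
    iti = 0.25
    onsets = baseline_window + 0.1 + np.arange(level_seq.size) * iti
    duration = float(onsets[-1] + iti)

    dt = 1.0 / sample_rate
    rate = np.full(int(round(duration / dt)), background_rate)
    for on, lev in zip(onsets, level_seq):
        if lev < cfg.deafened_threshold:
            continue
        r = rate_at_threshold + rate_per_db * (lev - cfg.deafened_threshold)
        i0 = int(round((on + _RESPONSE_LATENCY) / dt))
        i1 = int(round((on + stim_duration + _RESPONSE_LATENCY) / dt))
        rate[i0:i1] += r

    events = _thin(rng, rate, dt)
    voltage = rng.standard_normal(rate.size)
    template = 6.0 * np.array([0.3, 1.0, -0.6, 0.15])
    idx = np.minimum((events / dt).astype(int), rate.size - len(template) - 1)
    for k, w in enumerate(template):
        voltage[idx + k] += w

    trials = ToneTrialTable(
        onsets,
        np.zeros(level_seq.size),  # broadband: no single frequency
        level_seq,
        np.full(level_seq.size, stim_duration),
        baseline_window=baseline_window,
    )
    truth = {"threshold_db": float(cfg.deafened_threshold)}
    return RateLevelSession(trials, voltage, sample_rate, events, truth)


# ---------------------------------------------------------------------------
# walking audio
# ---------------------------------------------------------------------------

def simulate_walking_audio(
    cfg: SimConfig,
    duration: float = 2.0,
    sample_rate: float = 96_000.0,
    event_rate: float = 8.0,
    event_amplitude: float = 0.1,
    event_duration: float = 0.005,
    background_rms: float = 0.0005,  # noise-reduced baseline, well below events
    event_times: np.ndarray | None = None,
):
    """Footstep-like noise bursts on a low Gaussian background.

    Returns the audio trace and the true event onset times. Events are
    Hann-windowed white-noise bursts; doubling ``event_amplitude`` doubles
    the RMS inside the event windows.
    """
    rng = _rng(cfg, 5)
    n = int(round(duration * sample_rate))
    x = rng.standard_normal(n) * background_rms
    if event_times is None:
        n_ev = rng.poisson(event_rate * duration)
        times = np.sort(rng.uniform(0.05, duration - 0.05, n_ev))
        # enforce separation so events stay resolvable
        if times.size:
            keep = np.concatenate([[True], np.diff(times) > 4 * event_duration])
            times = times[keep]
    else:
        times = np.asarray(event_times, float)
    m = int(round(event_duration * sample_rate))
    win = np.hanning(m)
    for t0 in times:
        i = int(round(t0 * sample_rate))
        burst = event_amplitude * rng.standard_normal(m) * win
        x[i : i + m] += burst[: max(0, n - i)]
    return AudioTrace(sample_rate, x), times


def make_playback_ladder(reference: AudioTrace, ref_level_db: float, levels):
    """Scaled copies of a reference recording at the given dB levels."""
    return {
        float(lev): AudioTrace(
            reference.sample_rate,
            reference.samples * 10 ** ((lev - ref_level_db) / 20.0),
        )
        for lev in levels
    }
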