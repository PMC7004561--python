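"""Generator contracts: determinism, Poisson thinning correctness, bout
statistics, the attenuation rule, and audio event structure."""

import numpy as np
import pytest
from scipy import stats

from locomod import io
from locomod.core import ValidationError
from locomod.synth import (
    SimConfig,
    attenuate,
    gaussian_tuning,
    half_octave_grid,
    make_playback_ladder,
    simulate_ratelevel_unit,
    simulate_speed_trace,
    simulate_spontaneous_unit,
    simulate_tone_session,
    simulate_walking_audio,
)


class TestSpeedTrace:
    def test_zero_bout_rate_is_flat(self):
        cfg = SimConfig(seed=0, bout_rate=0.0, session_duration=60.0)
        speed, onsets = simulate_speed_trace(cfg)
        assert onsets.size == 0
        assert np.all(speed.speed == 0)

    def test_seed_determinism_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed=42, session_duration=60.0)
        for run in ("a", "b"):
            speed, bouts = simulate_speed_trace(cfg)
            train = simulate_spontaneous_unit(speed, bouts, cfg)
            io.write_speed(speed, tmp_path / f"speed_{run}.csv")
            io.write_spikes([train], tmp_path / f"spikes_{run}.csv")
        assert (tmp_path / "speed_a.csv").read_bytes() == (
            tmp_path / "speed_b.csv"
        ).read_bytes()
        assert (tmp_path / "spikes_a.csv").read_bytes() == (
            tmp_path / "spikes_b.csv"
        ).read_bytes()

    def test_bout_count_within_poisson_99_interval(self):
        cfg = SimConfig(seed=5, bout_rate=2.0, session_duration=600.0)
        _, onsets = simulate_speed_trace(cfg)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 20)
        assert lo <= onsets.size <= hi

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValidationError):
            simulate_speed_trace(SimConfig(session_duration=0.0))

    def test_speed_zero_between_bouts_and_voltage_in_range(self):
        cfg = SimConfig(seed=3, session_duration=120.0)
        speed, onsets = simulate_speed_trace(cfg)
        assert onsets.size > 0
        assert speed.voltage.min() >= 0 and speed.voltage.max() <= 2.5
        # first second precedes any bout: speed exactly 0
        assert np.all(speed.speed[: int(speed.sample_rate)] == 0)


class TestThinning:
    def test_zero_gain_gives_homogeneous_rate(self):
        cfg = SimConfig(seed=8, speed_gain=0.0, r0=15.0, session_duration=300.0)
        speed, _ = simulate_speed_trace(cfg)
        train = simulate_spontaneous_unit(speed, None, cfg)
        se = np.sqrt(cfg.r0 / cfg.session_duration)
        assert train.mean_rate == pytest.approx(cfg.r0, abs=3 * se)

    def test_positive_gain_raises_bout_rate(self):
        cfg = SimConfig(seed=9, speed_gain=1.0, r0=10.0, session_duration=600.0)
        speed, onsets = simulate_speed_trace(cfg)
        train = simulate_spontaneous_unit(speed, onsets, cfg)
        # rate inside bout plateaus ≈ r0 + g·peak_speed
        plateau = cfg.r0 + cfg.speed_gain * cfg.peak_speed
        counts, total = 0, 0.0
        for on in onsets:
            a, b = on + 0.3, on + 1.0  # plateau, past lead/ramp transients
            counts += train.count_in(a, b)
            total += b - a
        rate = counts / total
        se = np.sqrt(plateau / total)
        assert rate == pytest.approx(plateau, abs=4 * se)

    def test_negative_gain_rectifies_at_zero(self):
        cfg = SimConfig(
            seed=10, r0=5.0, speed_gain=-1.0, peak_speed=10.0,
            session_duration=300.0, bout_duration_mean=4.0,
        )
        speed, onsets = simulate_speed_trace(cfg)
        train = simulate_spontaneous_unit(speed, onsets, cfg)
        counts = sum(train.count_in(on + 0.3, on + 1.5) for on in onsets)
        # walking drive r0 + g·speed = 5 − 10 → rectified to 0
        assert counts == 0

    @pytest.mark.parametrize("seed,r0", [(1, 5.0), (2, 12.0), (3, 30.0)])
    def test_constant_window_rate_within_4_se(self, seed, r0):
        cfg = SimConfig(seed=seed, r0=r0, bout_rate=0.0, session_duration=200.0)
        speed, _ = simulate_speed_trace(cfg)
        train = simulate_spontaneous_unit(speed, None, cfg)
        se = np.sqrt(r0 / 200.0)
        assert train.mean_rate == pytest.approx(r0, abs=4 * se)


class TestAttenuationRule:
    def test_example_arithmetic_bf_vs_weak_tone(self):
        # stationary 40 Hz → walking 31.5 Hz (−21.25%); 10 Hz → 4.5 Hz (−55%)
        cfg = SimConfig(atten_gain=0.9, atten_floor=5.0)
        walk = attenuate([40.0, 10.0], cfg)
        assert walk == pytest.approx([31.5, 4.5])
        pct = 100 * (walk - np.array([40.0, 10.0])) / np.array([40.0, 10.0])
        assert pct == pytest.approx([-21.25, -55.0])

    def test_walking_never_exceeds_stationary(self):
        cfg = SimConfig(atten_gain=0.8, atten_floor=2.0)
        r = gaussian_tuning(half_octave_grid(), cfg, half_octave_grid())
        assert np.all(attenuate(r, cfg) <= r)

    def test_no_attenuation_identity(self):
        cfg = SimConfig(atten_gain=1.0, atten_floor=0.0)
        r = np.array([0.0, 10.0, 40.0])
        assert attenuate(r, cfg) == pytest.approx(r)

    def test_delta_tuning_hits_only_nearest_grid_frequency(self):
        grid = half_octave_grid()
        cfg = SimConfig(sigma_oct=0.0, bf_khz=15.0)  # nearest grid freq = 16
        r = gaussian_tuning(grid, cfg, grid)
        assert np.count_nonzero(r) == 1
        assert r[np.isclose(grid, 16.0)] == pytest.approx(cfg.peak_evoked)


class TestToneSession:
    def test_rejects_too_few_repeats(self):
        with pytest.raises(ValidationError):
            simulate_tone_session(SimConfig(), n_repeats=4)

    def test_onset_type_fires_only_early(self):
        cfg = SimConfig(seed=21, r0=2.0, speed_gain=0.0, bout_rate=0.0,
                        response_type="onset")
        sess = simulate_tone_session(cfg, n_repeats=40)
        on = sess.trials.onset_s[sess.trials.freq_khz == cfg.bf_khz]
        early = sum(sess.train.count_in(o + 0.005, o + 0.020) for o in on)
        late = sum(sess.train.count_in(o + 0.025, o + 0.055) for o in on)
        assert early > 5 * late

    def test_suppressed_type_drops_below_baseline(self):
        cfg = SimConfig(seed=22, r0=20.0, speed_gain=0.0, bout_rate=0.0,
                        response_type="suppressed")
        sess = simulate_tone_session(cfg, n_repeats=40)
        on = sess.trials.onset_s
        stim = sum(sess.train.count_in(o, o + 0.05) for o in on) / (0.05 * on.size)
        base = sum(sess.train.count_in(o - 0.1, o) for o in on) / (0.1 * on.size)
        assert stim < 0.5 * base

    def test_condition_labels_match_speed(self):
        cfg = SimConfig(seed=23)
        sess = simulate_tone_session(cfg, n_repeats=20)
        sp = sess.speed
        for i in range(0, sess.trials.n_trials, 17):
            o = sess.trials.onset_s[i]
            idx = int(o * sp.sample_rate)
            if sess.true_condition[i] == "walking":
                assert sp.speed[idx] > 0
            elif sess.true_condition[i] == "stationary":
                assert sp.speed[idx] == 0


class TestRateLevel:
    def test_levels_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            simulate_ratelevel_unit(SimConfig(), levels=[10.0, 20.0])

    def test_no_evoked_events_below_threshold(self):
        cfg = SimConfig(seed=31, deafened_threshold=70.0)
        sess = simulate_ratelevel_unit(cfg, n_repeats=20)
        t = sess.trials
        low = t.level_db < 70
        stim = sum(
            np.sum((sess.true_event_times >= o) & (sess.true_event_times < o + 0.06))
            for o in t.onset_s[low]
        )
        base_rate = 5.0  # background multi-unit rate
        # below threshold only background events appear in stimulus windows
        expect = base_rate * 0.06 * low.sum()
        assert stim < expect + 5 * np.sqrt(expect)


class TestWalkingAudio:
    def test_zero_events_rms_equals_background(self):
        cfg = SimConfig(seed=41)
        a, times = simulate_walking_audio(cfg, event_times=np.array([]),
                                          background_rms=0.01)
        assert times.size == 0
        assert np.sqrt(np.mean(a.samples**2)) == pytest.approx(0.01, rel=0.05)

    def test_doubling_event_amplitude_doubles_event_rms(self):
        cfg = SimConfig(seed=42)
        ev = np.array([0.5, 1.0, 1.5])
        a1, _ = simulate_walking_audio(cfg, event_times=ev, event_amplitude=0.1,
                                       background_rms=0.0)
        a2, _ = simulate_walking_audio(cfg, event_times=ev, event_amplitude=0.2,
                                       background_rms=0.0)
        r1 = np.sqrt(np.mean(a1.samples**2))
        r2 = np.sqrt(np.mean(a2.samples**2))
        assert r2 / r1 == pytest.approx(2.0, rel=1e-6)

    def test_ladder_scaling_is_exact_db(self):
        cfg = SimConfig(seed=43)
        ref, _ = simulate_walking_audio(cfg)
        ladder = make_playback_ladder(ref, 40.0, [20, 30, 40])
        assert np.allclose(ladder[40.0].samples, ref.samples)
        ratio = np.abs(ladder[20.0].samples).sum() / np.abs(ref.samples).sum()
        assert ratio == pytest.approx(0.1, rel=1e-9)
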