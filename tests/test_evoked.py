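"""PSTHs, response windows, evoked rates, percent change, response types,
and the multi-unit rate-level analysis."""

import numpy as np
import pytest

from locomod.behavior import segment_behavior, smooth_speed
from locomod.core import SpikeTrain, ToneTrialTable
from locomod.evoked import (
    FIXED_WINDOW,
    ONSET,
    SUPPRESSED,
    SUSTAINED,
    PSTH,
    analyze_evoked_unit,
    build_psth,
    classify_response_type,
    define_response_window,
    detect_multiunit_spikes,
    evoked_rate,
    percent_change,
    percent_change_unit,
    rate_level_curve,
)
from locomod.synth import (
    SimConfig,
    simulate_ratelevel_unit,
    simulate_tone_session,
)


class TestPSTH:
    def test_no_spikes_zero_everywhere(self):
        train = SpikeTrain("u", [], 10.0)
        p = build_psth(train, [1.0, 2.0, 3.0])
        assert np.all(p.rate == 0)

    def test_single_spike_peak_matches_gaussian_density(self):
        # one spike ~10 ms after onset in every trial (placed mid-bin so
        # float rounding cannot split spikes across adjacent 1 ms bins):
        # peak = 1/(σ√(2π)) ≈ 199.471 Hz
        onsets = np.arange(50) * 1.0 + 0.5
        train = SpikeTrain("u", onsets + 0.0105, 60.0)
        p = build_psth(train, onsets)
        expected = 1.0 / (0.002 * np.sqrt(2 * np.pi))
        assert p.rate.max() == pytest.approx(expected, abs=0.01)
        t_peak, _ = p.peak()
        assert t_peak == pytest.approx(0.0105, abs=0.002)

    def test_stationary_poisson_flat_near_true_rate(self):
        rng = np.random.default_rng(1)
        duration = 400.0
        times = np.sort(rng.uniform(0, duration, int(20 * duration)))
        train = SpikeTrain("u", times, duration)
        onsets = np.arange(2.0, duration - 2.0, 2.0)
        p = build_psth(train, onsets)
        # mean PSTH level over the whole window ≈ 20 Hz
        se = np.sqrt(20.0 / (onsets.size * 0.15))
        assert p.rate.mean() == pytest.approx(20.0, abs=3 * se)

    def test_integral_matches_mean_spike_count(self):
        rng = np.random.default_rng(2)
        onsets = np.arange(30) * 1.0 + 0.5
        spikes = np.sort(np.concatenate(
            [o + rng.uniform(0.0, 0.08, 4) for o in onsets]
        ))
        train = SpikeTrain("u", spikes, 40.0)
        p = build_psth(train, onsets, t_range=(-0.05, 0.15))
        integral = p.rate.sum() * p.bin_width
        assert integral == pytest.approx(4.0, rel=0.05)


class TestResponseWindow:
    def _psth_with_peak(self, t_peak):
        time = np.arange(-0.05, 0.1, 0.001)
        rate = np.exp(-((time - t_peak) ** 2) / (2 * 0.004**2)) * 100
        return PSTH(time, rate, 20)

    def test_peak_at_12_ms(self):
        w = define_response_window(self._psth_with_peak(0.012))
        assert w == (pytest.approx(0.007, abs=1e-3), pytest.approx(0.019, abs=1e-3))

    def test_peak_at_5_ms_boundary(self):
        w = define_response_window(self._psth_with_peak(0.005))
        assert w == (pytest.approx(0.0, abs=1e-3), pytest.approx(0.012, abs=1e-3))

    def test_fixed_mode_ignores_peak(self):
        w = define_response_window(self._psth_with_peak(0.030), mode="fixed15")
        assert w == FIXED_WINDOW

    def test_flat_psth_returns_none(self):
        time = np.arange(-0.05, 0.1, 0.001)
        flat = PSTH(time, np.zeros(time.size), 20)
        assert define_response_window(flat) is None


class TestEvokedRate:
    def test_window_50_baseline_10_gives_40(self):
        onsets = np.arange(10) * 1.0 + 0.5
        spikes = []
        for o in onsets:
            spikes.append(o - 0.05)  # 1 spike in 0.1 s baseline → 10 Hz
            spikes.append(o + 0.01)  # 1 spike in 0.02 s window → 50 Hz
        train = SpikeTrain("u", np.sort(spikes), 12.0)
        er = evoked_rate(train, onsets, (0.0, 0.02), 0.1)
        assert er.r_evoked == pytest.approx(40.0)
        assert er.spontaneous == pytest.approx(10.0)

    def test_equal_rates_not_significant(self):
        onsets = np.arange(10) * 1.0 + 0.5
        spikes = []
        for o in onsets:
            spikes += [o - 0.05, o + 0.05]  # 10 Hz in both 0.1 s windows
        train = SpikeTrain("u", np.sort(spikes), 12.0)
        er = evoked_rate(train, onsets, (0.0, 0.1), 0.1)
        assert er.r_evoked == 0.0
        assert not er.significant

    def test_power_on_simulated_onset_unit(self):
        cfg = SimConfig(seed=55, r0=5.0, speed_gain=0.0, bout_rate=0.0,
                        response_type="onset")
        sess = simulate_tone_session(cfg, n_repeats=100)
        m = sess.trials.freq_khz == 16.0
        er = evoked_rate(sess.train, sess.trials.onset_s[m], (0.005, 0.020), 0.1)
        assert er.significant
        assert er.r_evoked == pytest.approx(cfg.peak_evoked, rel=0.2)


class TestPercentChange:
    def test_halving_is_minus_50(self):
        assert percent_change(40.0, 20.0) == pytest.approx(-50.0)

    def test_equal_rates_zero(self):
        assert percent_change(15.0, 15.0) == 0.0

    def test_unit_level_ratio_of_sums(self):
        # (40→30, 10→2): (32 − 50)/50 = −36%
        assert percent_change_unit([40.0, 10.0], [30.0, 2.0]) == pytest.approx(-36.0)

    def test_unit_level_sum_of_percent_variant(self):
        out = percent_change_unit([40.0, 10.0], [30.0, 2.0], mode="sum_of_percent")
        assert out == pytest.approx(-105.0)


class TestResponseTypeRecovery:
    @pytest.mark.parametrize("rtype,expected", [
        ("onset", ONSET), ("sustained", SUSTAINED), ("suppressed", SUPPRESSED),
    ])
    def test_generator_label_recovered(self, rtype, expected):
        cfg = SimConfig(seed=60, r0=20.0, speed_gain=0.0, bout_rate=6.0,
                        response_type=rtype)
        sess = simulate_tone_session(cfg, n_repeats=60)
        segs = segment_behavior(smooth_speed(sess.speed))
        res = analyze_evoked_unit(sess.train, sess.trials, segs)
        assert res.response_type == expected


class TestMultiUnit:
    def test_silent_trace_no_events(self):
        assert detect_multiunit_spikes(np.zeros(1000), 10_000.0).size == 0

    def test_injected_spikes_recovered_within_half_ms(self):
        rng = np.random.default_rng(3)
        fs = 10_000.0
        v = rng.standard_normal(50_000)
        true_t = np.arange(0.5, 4.5, 0.1)
        for t in true_t:
            v[int(t * fs)] += 8.0
        det = detect_multiunit_spikes(v, fs)
        # a noise crossing just before a spike can eat it via the dead time,
        # so demand recovery of nearly all injected events
        hits = sum(np.min(np.abs(det - t)) < 0.0005 for t in true_t)
        assert hits >= 0.95 * true_t.size

    def test_dead_time_enforced(self):
        fs = 10_000.0
        v = np.zeros(1000)
        v[100:104] = 10.0  # one burst of consecutive crossings
        v[500] = 10.0
        det = detect_multiunit_spikes(v + 1e-6 * np.random.default_rng(0).standard_normal(1000), fs)
        assert det.size == 2


class TestRateLevel:
    @pytest.mark.parametrize("threshold", [30.0, 70.0])
    def test_configured_threshold_recovered(self, threshold):
        cfg = SimConfig(seed=70, deafened_threshold=threshold)
        sess = simulate_ratelevel_unit(cfg, n_repeats=30)
        bws = [(on - 0.1, on) for on in sess.trials.onset_s]
        ev = detect_multiunit_spikes(sess.voltage, sess.sample_rate,
                                     baseline_windows=bws)
        rl = rate_level_curve(ev, sess.trials)
        assert rl.hearing_threshold == threshold
        # monotone-ish growth above threshold
        above = rl.levels >= threshold
        assert np.all(np.diff(rl.peak_rate[above]) > -20)

    def test_silent_site_threshold_missing(self):
        trials = ToneTrialTable(
            np.arange(20) * 0.25 + 0.2,
            np.zeros(20), np.repeat([30.0, 60.0], 10)[np.argsort(np.tile(np.arange(10), 2), kind="stable")],
            np.full(20, 0.05),
        )
        rl = rate_level_curve(np.array([]), trials)
        assert rl.hearing_threshold is None


class TestUnitAnalysis:
    def test_window_shared_across_frequencies_and_conditions(self):
        cfg = SimConfig(seed=80, r0=8.0, speed_gain=0.0)
        sess = simulate_tone_session(cfg, n_repeats=60)
        segs = segment_behavior(smooth_speed(sess.speed))
        res = analyze_evoked_unit(sess.train, sess.trials, segs)
        assert res.response_window is not None  # single window reused everywhere
        assert res.best_frequency == cfg.bf_khz

    def test_sliding_and_fixed_windows_agree_on_onset_units(self):
        rs, rf = [], []
        for s in range(4):
            cfg = SimConfig(seed=90 + s, r0=8.0, speed_gain=0.0,
                            response_type="onset")
            sess = simulate_tone_session(cfg, n_repeats=60)
            segs = segment_behavior(smooth_speed(sess.speed))
            a = analyze_evoked_unit(sess.train, sess.trials, segs, window_mode="peak")
            b = analyze_evoked_unit(sess.train, sess.trials, segs, window_mode="fixed15")
            sa = a.table.query("condition == 'stationary'").sort_values("freq_khz")
            sb = b.table.query("condition == 'stationary'").sort_values("freq_khz")
            rs += list(sa.r_evoked_hz)
            rf += list(sb.r_evoked_hz)
        assert np.corrcoef(rs, rf)[0, 1] > 0.9

    def test_nonbf_attenuated_more_than_bf_across_population(self):
        # subtractive attenuation removes a larger fraction of the weaker
        # non-BF responses; the paired population contrast must be negative
        bf_pct, nonbf_pct = [], []
        for s in range(12):
            cfg = SimConfig(seed=200 + s, r0=8.0, speed_gain=0.0, bout_rate=8.0,
                            bout_duration_mean=3.0, atten_floor=12.0)
            sess = simulate_tone_session(cfg, n_repeats=250)
            segs = segment_behavior(smooth_speed(sess.speed))
            res = analyze_evoked_unit(sess.train, sess.trials, segs)
            pf = res.pct_change_by_freq.dropna(subset=["pct_change"])
            bf_rows = pf[pf.freq_khz == res.best_frequency]
            non_bf = pf[pf.freq_khz != res.best_frequency]
            if len(bf_rows) and len(non_bf):
                bf_pct.append(bf_rows["pct_change"].iloc[0])
                nonbf_pct.append(non_bf["pct_change"].mean())
        diff = np.asarray(nonbf_pct) - np.asarray(bf_pct)
        assert len(diff) >= 8
        assert diff.mean() < -5.0
        assert (diff < 0).mean() >= 0.6
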