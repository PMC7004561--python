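"""End-to-end orchestration: simulate or load a cohort, run every
analysis stage, apply the group-level statistics, and emit a structured
study report plus per-stage CSV tables.

Group comparisons screen each sample with the Lilliefors normality test
at α = 0.05 and fall back to the matching non-parametric test when any
group deviates from normality.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from . import behavior, evoked, latency, spontaneous, synth, tuning
from .core import (
    STATIONARY,
    WALKING,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "compare_groups",
    "compare_many",
    "one_sample_test",
    "StudyReport",
    "run_pipeline",
]


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    x = np.asarray(x, float)
    if x.size < 4 or np.std(x) == 0:
        return False  # cannot certify normality on degenerate samples
    _, p = lilliefors(x, dist="norm")
    return p >= alpha


def compare_groups(
    values_a, values_b, mode: str = "auto", paired: bool = False
):
    """Two-group comparison → (test_name, statistic, p).

    ``auto`` runs the Lilliefors screen on both groups and uses the
    parametric test only when neither deviates from normality; the
    non-parametric alternatives are the Wilcoxon signed-rank (paired) and
    rank-sum (unpaired) tests.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need at least 2 values per group")
    if mode == "auto":
        mode = "t" if (_is_normal(a) and _is_normal(b)) else "wilcoxon"
    if mode == "t":
        if paired:
            s, p = stats.ttest_rel(a, b)
            return "paired t-test", float(s), float(p)
        s, p = stats.ttest_ind(a, b)
        return "t-test", float(s), float(p)
    if mode == "wilcoxon":
        if paired:
            s, p = stats.wilcoxon(a, b)
            return "Wilcoxon signed-rank", float(s), float(p)
        s, p = stats.ranksums(a, b)
        return "Wilcoxon rank-sum", float(s), float(p)
    raise ValidationError(f"unknown mode {mode!r}")


def compare_many(groups, mode: str = "auto"):
    """k-group comparison → (test_name, statistic, p); ANOVA or
    Kruskal-Wallis after the normality screen."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise InsufficientDataError("need ≥2 groups with ≥2 values each")
    if mode == "auto":
        mode = "anova" if all(_is_normal(g) for g in groups) else "kruskal"
    if mode == "anova":
        s, p = stats.f_oneway(*groups)
        return "one-way ANOVA", float(s), float(p)
    if mode == "kruskal":
        s, p = stats.kruskal(*groups)
        return "Kruskal-Wallis", float(s), float(p)
    raise ValidationError(f"unknown mode {mode!r}")


def one_sample_test(values, popmean: float = 0.0, mode: str = "auto"):
    """One-sample location test against ``popmean``."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 values")
    if mode == "auto":
        mode = "t" if _is_normal(x) else "wilcoxon"
    if mode == "t":
        s, p = stats.ttest_1samp(x, popmean)
        return "one-sample t-test", float(s), float(p)
    s, p = stats.wilcoxon(x - popmean)
    return "one-sample Wilcoxon signed-rank", float(s), float(p)


# ---------------------------------------------------------------------------
# study report
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Structured summary of a cohort run; every number traces back to a
    row of the stage CSVs via unit ids."""

    config: dict
    spontaneous: dict = field(default_factory=dict)
    latency: dict = field(default_factory=dict)
    evoked: dict = field(default_factory=dict)
    tuning: dict = field(default_factory=dict)
    group_tests: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_jsonable)

    def to_text(self) -> str:
        lines = ["Locomotion-modulation study report", "=" * 36]
        sp = self.spontaneous
        if sp:
            lines += [
                f"Spontaneous modulation (n = {sp['n_units']}):",
                f"  increased {sp['n_increased']}, decreased {sp['n_decreased']}, "
                f"no change {sp['n_no_change']}",
            ]
        la = self.latency
        if la:
            med = la["median_latency_s"]
            med_txt = "n/a" if med is None else f"{med * 1000:.0f} ms"
            lines.append(
                f"Modulation latency: {la['n_qualified']} qualified units, "
                f"median {med_txt}"
            )
        ev = self.evoked
        if ev:
            lines.append(
                f"Evoked modulation (n = {ev['n_units']}): mean percent change "
                f"{ev['mean_pct_change']:.1f} ± {ev['sem_pct_change']:.1f}%, "
                f"{ev['fraction_attenuated'] * 100:.0f}% attenuated"
            )
        tu = self.tuning
        if tu and tu["n_units"]:
            lines.append(
                f"Tuning: mean width {tu['mean_width_stat']:.2f} oct stationary, "
                f"{tu['mean_width_walk']:.2f} oct walking "
                f"(mean change {tu['mean_width_change']:.2f} oct); "
                f"BF unchanged in {tu['n_bf_unchanged']}/{tu['n_units']} units"
            )
        for t in self.group_tests:
            lines.append(
                f"  [{t['name']}] {t['test']}: stat = {t['statistic']:.3g}, "
                f"p = {t['p']:.3g} (n = {t['n']})"
            )
        return "\n".join(lines)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


# ---------------------------------------------------------------------------
# cohort simulation + full run
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "n_units": 18,  # spontaneous cohort size
    "frac_increase": 0.5,  # positive-gain units
    "frac_decrease": 0.25,  # negative-gain units (rest: zero gain)
    "session_duration": 300.0,
    "r0": 20.0,
    "n_tone_units": 10,
    "tone_repeats": 100,
    "n_perm": 1000,
    "n_boot": 500,
    "alpha": 0.01,
}


def _spontaneous_stage(cfg: dict):
    rng = np.random.default_rng([cfg["seed"], 101])
    n = int(cfg["n_units"])
    if n < 1:
        raise ValidationError("empty cohort")
    n_inc = int(round(cfg["frac_increase"] * n))
    n_dec = int(round(cfg["frac_decrease"] * n))
    gains, truth = [], []
    base = synth.SimConfig(
        seed=cfg["seed"],
        session_duration=cfg["session_duration"],
        r0=cfg["r0"],
    )
    for i in range(n):
        # heterogeneous coupling strengths: excited units at least double
        # their rate at peak speed, suppressed units at least halve it
        if i < n_inc:
            g = rng.uniform(1.0, 4.0) * base.r0 / base.peak_speed
            lab = spontaneous.INCREASED
        elif i < n_inc + n_dec:
            g = -rng.uniform(0.5, 0.75) * base.r0 / base.peak_speed
            lab = spontaneous.DECREASED
        else:
            g, lab = 0.0, spontaneous.NO_CHANGE
        gains.append(g)
        truth.append(lab)

    spont_rows, lat_rows = [], []
    for i, g in enumerate(gains):
        ucfg = base.with_(seed=int(rng.integers(2**31)), speed_gain=g)
        speed, _ = synth.simulate_speed_trace(ucfg)
        train = synth.simulate_spontaneous_unit(speed, None, ucfg, unit_id=f"u{i:03d}")
        smoothed = behavior.smooth_speed(speed)
        segments = behavior.segment_behavior(smoothed)
        try:
            res = spontaneous.analyze_spontaneous_unit(
                train, segments, speed=smoothed,
                alpha=cfg["alpha"], n_perm=cfg["n_perm"],
                seed=int(rng.integers(2**31)),
            )
            row = res.to_row()
        except InsufficientDataError:
            row = {"unit_id": train.unit_id, "category": "insufficient_data"}
        row["true_category"] = truth[i]
        spont_rows.append(row)

        onsets = behavior.detect_locomotion_onsets(speed, segments)
        lat = latency.analyze_latency_unit(
            train, onsets, segments, n_boot=cfg["n_boot"],
            seed=int(rng.integers(2**31)),
        )
        lat_rows.append(lat.to_row())
    return pd.DataFrame(spont_rows), pd.DataFrame(lat_rows)


def _evoked_stage(cfg: dict):
    rng = np.random.default_rng([cfg["seed"], 202])
    rows, tuning_rows = [], []
    types = ["onset", "sustained"]
    for i in range(int(cfg["n_tone_units"])):
        ucfg = synth.SimConfig(
            seed=int(rng.integers(2**31)),
            r0=8.0,
            speed_gain=0.0,
            bout_rate=8.0,
            bout_duration_mean=3.0,
            response_type=types[i % len(types)],
            bf_khz=float(8.0 * 2 ** ((i % 4) / 2)),
        )
        sess = synth.simulate_tone_session(ucfg, n_repeats=int(cfg["tone_repeats"]))
        smoothed = behavior.smooth_speed(sess.speed)
        segments = behavior.segment_behavior(smoothed)
        try:
            res = evoked.analyze_evoked_unit(
                sess.train, sess.trials, segments
            )
        except InsufficientDataError:
            continue
        rows.append(
            {
                "unit_id": f"t{i:03d}",
                "bf_khz": res.best_frequency,
                "true_bf_khz": ucfg.bf_khz,
                "response_type": res.response_type,
                "true_type": ucfg.response_type,
                "pct_change": res.pct_change_unit,
                "sum_r_evoked_stat": float(
                    res.table.query("condition == @STATIONARY").r_evoked_hz.sum()
                ),
            }
        )
        tuning_rows.append(_tuning_row(f"t{i:03d}", res))
    return pd.DataFrame(rows), pd.DataFrame([r for r in tuning_rows if r])


def _tuning_row(unit_id: str, res: evoked.EvokedUnitResult):
    curves = {}
    for c in (STATIONARY, WALKING):
        sub = res.table[res.table.condition == c].sort_values("freq_khz")
        if sub.empty:
            return None
        curves[c] = tuning.TuningCurve(
            sub.freq_khz.to_numpy(),
            sub.r_evoked_hz.to_numpy(),
            sub.significant.to_numpy(),
            condition=c,
        )
    tw_s = tuning.tuning_width(curves[STATIONARY])
    tw_w = tuning.tuning_width(curves[WALKING])
    bf_s = res.best_frequency
    peaks_w = curves[WALKING].response
    bf_w = tuning.best_frequency(
        curves[WALKING].freq_khz, peaks_w, curves[WALKING].responsive
    )
    return {
        "unit_id": unit_id,
        "width_stat_oct": tw_s.width,
        "width_walk_oct": tw_w.width,
        "width_change_oct": tuning.width_change(tw_s.width, tw_w.width),
        "bf_stat_khz": bf_s,
        "bf_walk_khz": bf_w,
        "bf_shift_oct": tuning.bf_change(bf_s, bf_w) if bf_w else np.nan,
    }


def run_pipeline(config: dict | None = None, out_dir=None) -> StudyReport:
    """Run every stage on a simulated cohort and assemble the report.

    ``config`` overrides :data:`DEFAULT_CONFIG`; with ``out_dir`` the
    stage CSVs, the JSON report and a run log of every parameter are
    written there. Deterministic given the seed.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    if cfg["n_units"] < 1 and cfg["n_tone_units"] < 1:
        raise ValidationError("empty cohort")

    report = StudyReport(config=dict(cfg))
    spont_df, lat_df = _spontaneous_stage(cfg)
    ev_df, tun_df = _evoked_stage(cfg)

    counts = spont_df["category"].value_counts()
    report.spontaneous = {
        "n_units": int(len(spont_df)),
        "n_increased": int(counts.get(spontaneous.INCREASED, 0)),
        "n_decreased": int(counts.get(spontaneous.DECREASED, 0)),
        "n_no_change": int(counts.get(spontaneous.NO_CHANGE, 0)),
    }

    lat_ok = lat_df[lat_df.qualified.fillna(False)]
    lats = lat_ok.latency_s.dropna().to_numpy(float)
    report.latency = {
        "n_units": int(len(lat_df)),
        "n_qualified": int(len(lat_ok)),
        "median_latency_s": float(np.median(lats)) if lats.size else None,
        "n_negative": int((lats < 0).sum()),
        "by_direction": {
            d: float(np.median(lat_ok[lat_ok.direction == d].latency_s.dropna()))
            for d in ("positive", "negative")
            if (lat_ok.direction == d).any()
        },
    }

    pct = ev_df["pct_change"].dropna().to_numpy(float) if len(ev_df) else np.array([])
    report.evoked = {
        "n_units": int(len(ev_df)),
        "mean_pct_change": float(pct.mean()) if pct.size else float("nan"),
        "sem_pct_change": float(pct.std(ddof=1) / np.sqrt(pct.size))
        if pct.size > 1
        else float("nan"),
        "fraction_attenuated": float((pct < 0).mean()) if pct.size else float("nan"),
        "type_counts": ev_df.response_type.value_counts().to_dict()
        if len(ev_df)
        else {},
    }

    if len(tun_df):
        nonzero = tun_df[tun_df.width_walk_oct > 0]
        report.tuning = {
            "n_units": int(len(nonzero)),
            "n_width_zero_walk": int((tun_df.width_walk_oct == 0).sum()),
            "mean_width_stat": float(nonzero.width_stat_oct.mean()),
            "mean_width_walk": float(nonzero.width_walk_oct.mean()),
            "mean_width_change": float(nonzero.width_change_oct.mean()),
            "n_bf_unchanged": int((nonzero.bf_shift_oct.abs() < 1e-9).sum()),
        }
    else:
        report.tuning = {"n_units": 0}

    tests = []
    if pct.size >= 2:
        name, s, p = one_sample_test(pct, 0.0)
        tests.append(
            {"name": "evoked percent change vs 0", "test": name,
             "statistic": s, "p": p, "n": int(pct.size)}
        )
        strength = ev_df.dropna(subset=["pct_change"]).sort_values(
            "sum_r_evoked_stat"
        )
        half = len(strength) // 2
        if half >= 2:
            name, s, p = compare_groups(
                strength["pct_change"].iloc[:half], strength["pct_change"].iloc[half:]
            )
            tests.append(
                {"name": "weaker vs stronger responses", "test": name,
                 "statistic": s, "p": p, "n": int(len(strength))}
            )
    if len(tun_df) and (tun_df.width_walk_oct > 0).sum() >= 2:
        wc = tun_df.loc[tun_df.width_walk_oct > 0, "width_change_oct"].to_numpy()
        name, s, p = one_sample_test(wc, 0.0, mode="wilcoxon")
        tests.append(
            {"name": "tuning width change vs 0", "test": name,
             "statistic": s, "p": p, "n": int(wc.size)}
        )
    report.group_tests = tests

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spont_df.to_csv(out / "spont_results.csv", index=False)
        lat_df.to_csv(out / "latency_results.csv", index=False)
        ev_df.to_csv(out / "evoked_results.csv", index=False)
        tun_df.to_csv(out / "tuning_results.csv", index=False)
        (out / "report.json").write_text(report.to_json())
        (out / "report.txt").write_text(report.to_text() + "\n")
        (out / "run_log.json").write_text(json.dumps(cfg, indent=2, default=_jsonable))
    return report
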