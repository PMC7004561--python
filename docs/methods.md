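# Methods

This note documents the models, parameter choices, and numerical
conventions behind `locomod`, and what the synthetic-data validation does
and does not establish about real recordings.

## Conventions

Time is in seconds throughout; every interval is half-open `[start, end)`
so boundary spikes are counted once. Frequencies are stored in kHz and
mapped to log2(kHz) ("octave position") only inside tuning computations.
dB values on the playback ladder are relative labels, not calibrated SPL.

## Behavioural segmentation

The rotary-encoder speed channel is smoothed with a unit-sum hanning
window (default 200 ms, reflect padding, which preserves constants
exactly) and thresholded at 2 cm/s; walking is `smoothed speed >
threshold`. Brief movement blips are retained unless a minimum-duration
merge is requested, because no principled blip-removal rule exists.

Locomotion onset uses the accumulated *travel*: within each walking bout
preceded by at least 1 s of stationary behaviour ("clear onset"), the
onset is the first sample at which unwrapped voltage change since the
bout start reaches 2% of the 2.5 V range. The encoder calibration is
2.5 V per 4.5 cm of travel, so the criterion corresponds to 0.9 mm. Note
the two time marks are not identical: the label transition comes from the
smoothed speed (which leads the raw movement by up to ~100 ms), while the
travel criterion is met a few tens of ms after true movement start; on
simulated sessions the detected onsets sit ~40–70 ms after the true bout
starts, well within the ±150 ms recovery bound asserted in the tests.

## Spontaneous modulation

Per-condition rates come from non-overlapping 1 s chunks (or trial
baselines) lying wholly inside one behavioural interval. The permutation
test pools both groups, resamples group assignments (default 1000
permutations) and uses the bias-free estimator p = (1 + k)/(n_perm + 1)
on the absolute mean difference; a signed two-tailed variant is available
(`statistic="signed"`). The pooled values are sorted before permuting so
relabeling the groups cannot change the p-value. No multiple-testing
correction is applied across units — α = 0.01 is per neuron.

The rate–speed correlation smooths a 10 ms-binned spike-count series with
the same 200 ms hanning as the speed channel, putting both series on one
bandwidth before computing Pearson r.

## Onset-triggered averaging and latency

The firing rate is estimated on 5 ms bins with a 25 ms-SD Gaussian — wide
enough to tame single-trace Poisson variance, narrow enough to resolve
~100 ms latencies. Segments of this rate in a window (default ±1 s)
around each onset are averaged; the 95% CI is the 2.5/97.5 percentile of
1000 bootstrap resamples of segments. The stationary mean and SD are
computed from the *same smoothed-rate object* restricted to stationary
intervals, since that is the object whose deviation is tested.

Modulation onset is the first lattice time at which the CI bound nearer
the stationary mean crosses mean ± 2·SD (the conservative reading;
direction is taken from the larger excursion of the mean trace), and must
stay beyond the band for ≥50 ms. A unit qualifies with ≥10 usable onsets
and a sustained crossing; otherwise it is reported as "insufficient
onsets" or "weak modulation". Because the OTA time axis is relative to
onset(L), the detected crossing time *is* the latency.

Two opposing measurement delays partially cancel in this estimate: the
travel criterion places onset(L) ~40–60 ms after movement start, and the
2-SD crossing lags the true rate change by a comparable amount when the
modulation is strong. The validation cohort therefore uses strongly
modulated units (baseline 8 Hz, drive +90 Hz at peak speed) and a 0.1 s
acceleration ramp — fast, as real mice accelerate — under which simulated
leads of 60–200 ms are recovered with a median error under ~20 ms. For
weakly modulated units the crossing delay grows and latencies bias toward
zero; such units mostly fail qualification, mirroring the fact that
latency is only measurable in units with a clear onset-triggered average.

## Tone-evoked analysis

PSTHs use 1 ms bins and a truncated (±6σ) unit-sum Gaussian of σ = 2 ms,
built on a padded range and cropped so edges are undistorted; with one
spike per trial in a single bin the peak equals 1/(σ√2π) ≈ 199.47 Hz to
within discretisation error < 0.01 Hz.

The response window is [peak − 5 ms, peak + 7 ms] of the stationary PSTH
at the best frequency (the frequency with the greatest peak; ties break
to the lower frequency) and is reused for *every* stimulus and condition
of that unit; a fixed 5–20 ms window is available as `window_mode=
"fixed15"`. A trial enters a condition only when its baseline+stimulus
epoch lies wholly inside one behavioural interval, and a frequency enters
only with ≥5 trials per condition. Significance is a two-sided paired
t-test (α = 0.05) between window and baseline rates, counted in the
excitatory direction; suppression is tested separately. Constant
differences yield p = 1.

Percent change per frequency requires a stationary evoked rate of at
least 1 Hz (smaller denominators are flagged unreliable and excluded);
the unit-level value is the percent change of frequency-summed evoked
rates (ratio of sums), which stays bounded — the literal sum of
per-frequency percentages is available as `pct_mode="sum_of_percent"`.

Temporal types: suppressed if the stimulus-period rate is significantly
below baseline; otherwise onset if the mean rate over the last half of
the stimulus falls below baseline + 25% of (peak − baseline), else
sustained. The 25% criterion is a package convention — the classes are
standard but no quantitative boundary is, so the threshold is exposed.

Multi-unit events are |v| threshold crossings at 3× the baseline-noise SD
with a 1 ms dead time. Rate-level curves take the 2 ms-smoothed PSTH peak
minus baseline per level; the hearing threshold is the lowest level with
a significant excitatory response whose peak evoked rate is ≥20% of the
site's maximum. The effect-size floor is deliberate: with ~5 silent
levels per site an isolated paired-test false positive (~2.5% per level)
would otherwise corrupt a noticeable fraction of threshold estimates.

## Tuning width

Widths are four times the *square root* of the second central moment of
the rectified response profile along the octave axis — 4σ, which carries
octave units and matches the 0.5–5 octave range such widths span on
half-octave grids; the literal 4×variance variant is available
(`moment="4var"`) for sensitivity analysis. The computation is restricted
to contiguous runs of significantly excitatory frequencies; each run is
linearly interpolated (100 points per interval, original grid values
preserved exactly) before the moments are taken, and when several runs
exist the total width is the length of the union of the per-run segment
intervals (summed minus the overlap). `interpolate=False` computes the
moments on the raw grid samples instead (two equal responses ±1 octave
apart then form a two-point mass of width exactly 4.0 octaves, versus
2.309 for the interpolated uniform band).

Width is exactly invariant to multiplying all responses by a positive
constant and to rigid translation along the octave axis. Subtractive
attenuation of a Gaussian tuning curve provably shrinks 4σ while leaving
the mode, hence the best frequency, unchanged — the mechanism behind the
population sharpening result.

## Walking-sound analysis

Bandpass: 4th-order Butterworth, 1–25 kHz, applied forward–backward
(zero phase) so event timing is unskewed. Events are defined once, on the
reference (40 dB playback analogue) envelope — rectified waveform
smoothed with a 2 ms rectangular window — at 4% of its peak, and those
same intervals are reused on every compared trace. The level estimate is
the ladder rung with the nearest RMS (event-window or whole-trace scope;
both agree on the generator's default audio). The noise-reduction step
applied to real recordings is modelled only as a low generator background
(RMS well below the event threshold), not reproduced.

## Synthetic sessions

`SimConfig` defines the generative conditions. Behaviour: bouts from a
renewal process with a mean cycle of 60/bout_rate (default 6/min), normal
bout durations (2.5 ± 1 s), a trapezoidal speed profile reaching 15 cm/s
in 0.1 s, and gaps of at least 2 s so every bout has a clean onset.
Spikes are inhomogeneous Poisson, sampled by thinning against an explicit
rate bound, with rate(t) = max(0, r0 + g·speed(t + Δ)): the speed drive
is shifted *earlier* by the modulation lead Δ (default 100 ms), directly
creating the negative latency the latency stage must recover.

Tone responses follow R(f) = peak·exp(−(log2 f − log2 BF)²/(2σ²)) with
defaults BF = 16 kHz, σ = 0.45 octaves, peak = 60 Hz — a strong,
well-tuned midbrain unit. Walking trials are attenuated as
max(0, a·(R − s)) with a = 0.9, s = 5 Hz; the subtractive floor removes a
fixed rate before scaling, so weaker responses lose a larger fraction —
e.g. 40 → 31.5 Hz (−21.25%) at a strong tone but 10 → 4.5 Hz (−55%) at a
weak one. Onset-type units fire their evoked spikes in the first 15 ms,
sustained units throughout the stimulus, and suppressed units drop to 20%
of baseline during it (the suppression depth is a package convention).
Multi-unit rate-level streams put 6-SD biphasic deflections on unit
Gaussian noise, silent below the configured hearing threshold (30 dB
normal, 70 dB deafened) and linearly growing above it. Walking audio is
Hann-windowed noise bursts over a low Gaussian background.

Everything is reproducible: each generator draws from
`default_rng([seed, stream])`, and identical configurations produce
byte-identical CSV/WAV outputs.

### What the simulations do and do not show

The generator reproduces the *statistical structure* the analysis
assumes — Poisson spiking with speed-coupled rates, clean bout kinematics,
Gaussian log-frequency tuning, additive evoked responses. Real recordings
add non-Poisson variability (bursting, adaptation), sorting artefacts,
drifting baselines, irregular gait, and correlated noise across trials.
Passing recovery tests therefore validates the estimators' correctness
and calibration under the stated model, not robustness to every failure
mode of real data; the refractory-violation QC and the minimum-trial /
minimum-onset filters are the package's only defences against the latter.

## Validation problem sizes

The acceptance script and tests use desk-scale cohorts chosen to give
tight recovery statistics: 2000 null units for type-I calibration (the
(1+k)/(n+1) estimator at 1000 permutations rejects at 0.009–0.012),
120 units for direction recovery, ~34 units per lead (≈55 clean onsets
each over 600 s) for latency, 200 tone sessions of 150 repeats per
frequency (≈95 stationary / 50 walking trials per stimulus, the scale of
real sessions) for the sharpening analysis, and 50 rate-level sites of 50
repeats per level for threshold recovery.

## Known limitations

* Latency estimates are biased toward zero for weak modulations; only
  qualified units should be interpreted.
* The onset/sustained boundary and the suppressed-type generative form
  are package conventions; classifications near the boundary are
  sensitive to the 25% parameter.
* Percent-change values are unstable when stationary evoked rates
  approach the 1 Hz floor; such frequencies are excluded rather than
  winsorised.
* The source-data files accompanying published figures are not parsed;
  loaders for external schemas are out of scope.
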