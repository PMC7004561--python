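# locomod

Spike-train analysis of locomotion-related modulation in the auditory
midbrain.

When a head-fixed mouse walks on a treadmill, neurons in the inferior
colliculus (IC) change their firing even without any sound: some units
increase their spontaneous rate with running speed, others decrease it,
and the rate change can *precede* the first detectable movement. During
walking, tone-evoked responses are attenuated — more strongly for weak
responses than for strong ones — which sharpens frequency tuning across
the population. `locomod` implements the full analysis chain needed to
quantify these effects from treadmill electrophysiology, plus a synthetic
session generator so every stage can be exercised and validated without
any recordings.

It is aimed at systems/auditory neuroscientists analysing head-fixed
treadmill recordings: per-unit spike-time tables, a rotary-encoder speed
trace, tone-trial tables, and (optionally) microphone recordings of
walking sounds.

## What it computes

**Behaviour.** The treadmill speed is smoothed with a 200 ms hanning
window and thresholded at 2 cm/s into stationary/walking intervals.
Locomotion onset, onset(L), of each clean bout (≥1 s stationary before
it) is the time accumulated travel first reaches 2% of the 2.5 V encoder
range (<1 mm of travel).

**Spontaneous modulation.** Firing rates from 1 s chunks (or trial
baselines) falling wholly inside one behavioural condition are compared
with a two-tailed permutation test (1000 permutations of the group
labels; p = (1+k)/(n+1)). Each unit is classified at α = 0.01 as
increased / decreased / no-change, together with the rate–speed Pearson
correlation and the modulation index

    MI = (⟨r⟩walk − ⟨r⟩stat) / (⟨r⟩walk + ⟨r⟩stat)  ∈ [−1, 1].

**Modulation latency.** The smoothed firing rate is averaged across
locomotion onsets; a bootstrap (resampling onsets) gives a pointwise 95%
CI. Modulation onset, onset(M), is the first time the CI bound nearer the
stationary mean leaves the stationary mean ± 2 SD band, and
latency = onset(M) − onset(L); negative latency means the rate change
leads the movement.

**Tone-evoked responses.** PSTHs (1 ms bins, 2 ms Gaussian smoothing)
define a per-unit response window [peak − 5 ms, peak + 7 ms] at the best
frequency; the evoked rate is the window rate minus the pre-stimulus
baseline, its significance a paired t-test, and locomotion modulation is
100·(r_walk − r_stat)/r_stat per frequency and as a ratio of sums per
unit. Multi-unit streams are thresholded at 3× the baseline SD to build
rate-level functions and hearing thresholds.

**Frequency tuning.** Tuning curves on the log2-frequency axis are
linearly interpolated (100 points per interval); the tuning width is four
times the square root of the second moment about the response-weighted
centroid, in octaves, with split responsive segments summed minus their
overlap.

**Walking sounds.** Microphone traces are bandpass filtered (1–25 kHz),
events are detected on a 2 ms-smoothed envelope at 4% of the reference
peak, and the walking-sound level is the playback-ladder rung
(20–40 dB, 5 dB steps) with the nearest RMS.

## Worked example

Run the whole pipeline on a simulated cohort (18 spontaneous units: half
excited by locomotion, a quarter suppressed, a quarter uncoupled; 10
tone-driven units with subtractive locomotion attenuation):

```python
from locomod import pipeline
report = pipeline.run_pipeline({"seed": 3}, out_dir="out")
print(report.to_text())
```

```
Locomotion-modulation study report
====================================
Spontaneous modulation (n = 18):
  increased 9, decreased 4, no change 5
Modulation latency: 6 qualified units, median -50 ms
Evoked modulation (n = 10): mean percent change -27.3 ± 5.0%, 100% attenuated
Tuning: mean width 1.20 oct stationary, 0.88 oct walking (mean change -0.32 oct); BF unchanged in 9/9 units
  [evoked percent change vs 0] one-sample t-test: stat = -5.46, p = 0.000403 (n = 10)
  [weaker vs stronger responses] t-test: stat = -1.06, p = 0.321 (n = 10)
  [tuning width change vs 0] one-sample Wilcoxon signed-rank: stat = 6, p = 0.0547 (n = 9)
```

Reading the output: the permutation test recovers the generated 9/4/5
increased/decreased/no-change split exactly; the six units with strong
modulation and enough clean bouts yield a negative median latency (the
rate drive was generated leading movement); evoked rates drop by ~27% on
average during walking; and the subtractive attenuation narrows tuning by
0.32 octaves while every unit keeps its best frequency. Each summary
number can be recounted from the stage CSVs (`spont_results.csv`,
`latency_results.csv`, `evoked_results.csv`, `tuning_results.csv`)
written to `out/`.

The same stages are available from the shell:

```sh
locomod simulate --seed 4 --duration 120 --out-dir demo
locomod segment  --speed-csv demo/speed.csv --out-dir demo
locomod spont    --spikes-csv demo/spikes.csv --speed-csv demo/speed.csv \
                 --segments-csv demo/segments.csv --out demo/spont.csv
```

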