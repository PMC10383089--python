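# stepmax

Free-living analogues of the clinical six-minute and two-minute walk tests,
computed from event-format physical-behaviour data.

Thigh-worn activity monitors classify free-living behaviour into a sequence
of *events*: contiguous periods of sedentary time (sitting/lying), standing,
or single strides (two steps each). `stepmax` turns such event streams into
the **maximum n-minute step count** — the largest number of steps a person
accumulated in any window of length *n* during monitoring — and the
population measures built on it. The intended users are researchers in
physical-behaviour analytics and digital-biomarker development who want a
performance measure that does not require a supervised walk test.

## The measure

For a window duration *n* (30 s to 10 min by default), a search window is
slid across each day's *upright containers* (maximal standing+stepping
periods uninterrupted by sedentary events):

* a stride contributes its two steps iff its temporal midpoint lies inside
  the window, so a partially covered stepping bout contributes only the
  strides actually inside;
* if a sedentary event begins inside the window (a break in being upright),
  only stepping before that break counts;
* the window with the highest count wins; ties go to the window that
  accumulated the count in the shortest time, then to the earliest window.

The per-day maxima are aggregated over the valid days (> 10 h classified
activity **and** > 500 steps, strict) of the first observation period with
at least seven valid days. Derived measures include the step accumulation
rate (max count ÷ *n*, steps/min), the stepping-proportion availability
table (share of subjects whose best window was ≥ 100/95/90/80 % stepping),
the mean daily number of bouts at least *n* long, distribution shape
(normal iff |skew| < 2 and excess kurtosis < 7), and sex/month/correlation
comparisons.

The search is exact, not gridded: step counts only change when a stride
midpoint enters or leaves the window, so the finite set of windows anchored
at stride midpoints (plus stride onsets, for canonical starts) provably
contains the optimum. A dense-grid brute force is included as an
independent oracle.

Because the study-scale dataset this kind of analysis is run on is access
restricted, the package ships a seeded synthetic generator
(`stepmax.synth`) producing realistic free-living event streams —
log-normal sedentary blocks and bout durations, truncated-normal cadence, a
configurable fraction of "low-opportunity" subjects who never walk long
bouts — with exact ground-truth bookkeeping for every generated bout.

## Worked example

```
$ stepmax simulate --seed 42 --subjects 3 --out-dir cohort
INFO stepmax: wrote 3 subject files to cohort
$ stepmax compute cohort --out-dir out --durations 120,360
INFO stepmax: processed 3 subjects (0 excluded, 0 file warnings); wrote out/summaries.csv
$ stepmax report --summaries out/summaries.csv --manifest cohort/manifest.json --out-dir report
```

`out/summaries.csv` holds one row per subject (selected columns):

```
subject_id,valid_days,max_steps_120,rate_120,max_steps_360
S0001,7,258,129.0,682
S0002,7,272,136.0,686
S0003,7,272,136.0,580
```

Subject S0001's best two minutes of free-living walking contained 258 steps
(an accumulation rate of 129 steps/min); their best six minutes contained
682 steps (114 steps/min — lower, as a six-minute window can never beat
three times the best two-minute window). `report/stepping_proportions.csv`
is the availability table — the fraction of subjects whose best window at
each duration was at least the given proportion stepping:

```
duration_s,1.0,0.95,0.9,0.8
120.0,1.0,1.0,1.0,1.0
360.0,0.6666666666666666,0.6666666666666666,0.6666666666666666,1.0
```

All three subjects filled a two-minute window with continuous stepping;
only two of the three ever walked six minutes without interruption — the
availability gap that motivates preferring the two-minute window.
`report/report.json` adds distribution statistics and the cohort tests
(suppressed, with the reason logged, when groups are too small).

The same pipeline is available as a library: `read_events`,
`merge_strides_to_bouts`, `build_upright_containers`,
`max_n_minute_step_count`, `sweep_window_durations`, `summarise_subject`,
`stepping_proportion_table`, `distribution_stats`, `cohort_tests`.

## Event CSV dialect

UTF-8, RFC 4180, ISO 8601 timestamps (naive local time, days split at
midnight), one subject-observation per file:

```
subject_id,start_iso8601,duration_s,activity,steps
S0001,2023-03-06T00:00:00.000000,25842.962481,sedentary,0
S0001,2023-03-06T07:10:42.962481,11.297289,standing,0
S0001,2023-03-06T07:10:54.259770,1.126400,stride,2
```

Events must be contiguous (gap tolerance 1 ms; jitter up to 1 s can be
bridged on request); strides carry exactly two steps.

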