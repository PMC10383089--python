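# Methods

This note records the model, the algorithmic choices, and the open design
decisions behind `stepmax`, at the level of detail a maintainer or reviewer
needs to audit the numbers the package produces.

## Event model

The unit of input is an *event*: one contiguous period of a single activity
class — `sedentary` (sitting or lying), `standing`, or `stride` — with a
start time, a positive duration in seconds, and a step count (exactly 2 for
a stride, 0 otherwise). A subject's events must be sorted and contiguous:
the next event starts where the previous one ends, to within a gap
tolerance of 1 ms (real exports carry rounding jitter; gaps up to 1 s can
optionally be bridged by extending the earlier event). Overlaps are always
an error. Timestamps are naive local time; the calendar day (midnight to
midnight) is the unit of validity and of the per-day maxima. An event
spanning midnight is cut at the boundary; a cut stride's two steps follow
the fragment containing the stride's midpoint, so totals are conserved
exactly (at timestamp resolution, i.e. to the nanosecond).

Derived structures:

* **Stepping bout** — maximal run of temporally adjacent stride events;
  characterised by duration, step count (2 × strides) and mean cadence
  (steps per minute, `step_count / (duration/60)`).
* **Upright container** — maximal run of adjacent standing and stepping
  events uninterrupted by any sedentary event. Containers partition
  non-sedentary time; every bout lies wholly inside one container.

## The maximum n-minute step count

For a window duration `n` seconds, a window `[T, T + n)` scores:

* **counted strides** — strides whose midpoint lies in
  `[T, min(s*, T + n))`, where `s*` is the first sedentary onset strictly
  inside the window. The midpoint rule resolves partial coverage of a bout:
  strides are discrete, counted whole, and counts stay integral. The break
  rule means stepping after a return to sitting inside the window never
  counts; quiet standing inside the window does not truncate.
* `step_count` — summed steps of counted strides.
* `accumulation_time` — last counted stride's end minus first counted
  stride's start, capped at `n`.
* `stepping_time` — summed duration of counted strides, capped at
  `accumulation_time`.

The caps exist because a boundary stride counted by the midpoint rule can
poke out of the window by less than half a stride; capping keeps the
invariant `0 ≤ stepping_time ≤ accumulation_time ≤ n` while counting whole
strides. The selected window maximises `step_count`, breaking ties by
smallest `accumulation_time`, then earliest start.

### Exactness of the anchored search

The candidate set is the windows starting at every stride midpoint and
every stride start. Sufficiency of the midpoint anchors: take any window
`[T, T+n)` achieving the maximum and let `m1` be its first counted
midpoint. No sedentary onset lies in `(T, m1]` (such an onset would
truncate the window before `m1`). Shift the start right to `m1`: the first
onset after the start is unchanged, the right edge moves right, so every
previously counted midpoint is still counted — the count cannot decrease,
and at the maximum it cannot increase, so the counted set is identical.
Hence some midpoint-anchored window attains the maximum with the same
counted set, and therefore the same accumulation time. Stride-start
anchors are a superset added so that the earliest-start tie-break selects
windows aligned to stride onsets, which makes `stepping_time` equal `n`
exactly for a window of continuous stepping.

### The grid oracle and its resolution limit

`brute_force_max` evaluates every window start on a fixed grid (default
0.1 s) and applies the same scoring — an implementation-independent lower
bound used in testing. It is a *lower* bound because the set of starts
realising a given counted stride set is the interval `(m_last − n,
m_first]` (further bounded below by the last sedentary onset at or before
`m_last`), whose width `n − (m_last − m_first)` can be arbitrarily small;
when it is narrower than the grid, no grid point need fall inside it. On
seeded synthetic streams this happens for roughly 0.1 % of (stream,
duration) pairs at the 0.1 s grid. The acceptance tests therefore assert
that the grid oracle never exceeds the anchored search, that any
disagreement coincides with a placement interval narrower than the grid
(recomputed from the raw events, not from the search), and that refining
the grid below that width restores exact agreement. A second, pure-Python
reference implementation provides an independent exact check on small
streams.

### Structural inequalities

Two properties are tested on every generated stream:

* **Monotonicity** — for `m ≥ n`, the max `m`-window count is at least the
  max `n`-window count (extend the optimal `n`-window rightward: the first
  onset after the start is unchanged, the counted set can only grow).
* **Multiple-cover bound** — for integer `k`, `max_{kn} ≤ k · max_n`:
  partition the optimal `kn`-window into `k` consecutive `n`-windows; each
  counted stride's midpoint lands in exactly one part, and a stride counted
  before the `kn`-window's first break is also before each part's first
  break. Corollary: the 2-minute accumulation rate is ≥ the 6-minute rate
  for every subject — the per-subject form of the population ordering the
  measure is designed to exhibit.

## Day validity and observation selection

A day is valid iff it has **more than** 10 h of classified activity (sum of
all event durations) and **more than** 500 steps; the boundary day (exactly
10 h or exactly 500 steps) is invalid, following the strict wording of the
rule. Invalid days are retained in the day tables but excluded from all
maxima. Per subject, the first observation period (of up to two, six
months apart) with at least seven valid days is analysed; subjects with
none are reported as excluded with the reason. The month attached to a
summary is the month of the observation's first valid day.

## Availability (stepping-proportion) table

For each duration `n` and threshold `q ∈ {1.00, 0.95, 0.90, 0.80}`, the
proportion of subjects whose stepping time was at least `q·n`. Two
readings are implemented:

* `max_count_window` (default) — the stepping time *of the window in which
  the subject achieved their maximum step count*;
* `best_window` — the maximum stepping time over all windows (requires
  summaries built with `compute_best_stepping=True`; the same anchored
  search applies with summed stride duration as the objective, and the
  midpoint-anchor sufficiency argument carries over verbatim to any
  nonnegative per-stride weight).

Proportions are compared with 0.5 ms slack so exact full coverage is not
lost to float round-off. Monotonicity in the threshold holds in both modes
by set inclusion; monotonicity in `n` (at nested durations) is guaranteed
only in `best_window` mode and is property-tested there.

## Distribution shape and cohort tests

Skewness and excess kurtosis default to the bias-corrected estimators
(adjusted Fisher–Pearson `G1`; `G2 = ((n+1)g2 + 6)(n−1)/((n−2)(n−3))`),
with the uncorrected moment ratios `g1, g2` behind `corrected=False`; the
choice is fixed here because upstream tooling in this area typically cites
a package default without printing a formula. A distribution is classified
*normal* iff |skew| < 2 and kurtosis < 7. Constant samples leave both
undefined and are flagged degenerate. Group comparisons use the
pooled-variance two-sample t (sex), one-way ANOVA with (k−1, N−k) degrees
of freedom (month), Pearson correlation with n−2 df (2-min vs 6-min
maxima), and the paired t for accumulation rates across durations — the
unpaired variant is also provided because published analyses of paired
rate columns sometimes report unpaired degrees of freedom. p-values are
reported to 4 decimals; no multiple-testing correction is applied.

## Synthetic generator

Each generated day is: overnight sedentary block, then a waking window
(07:00–23:00 by default) filled by alternating sedentary blocks and
upright containers, then sedentary to midnight — so a generated day has
24 h of classified time, as thigh-worn monitors are worn continuously.
A container is quiet standing interleaved with `Poisson(1.5)` stepping
bouts; a bout is a run of identical stride events (duration `120/cadence`
seconds each, on a microsecond grid so ground truth matches the emitted
events exactly). Defaults, chosen once as a realistic free-living
structure for older adults:

| parameter | default | meaning |
|---|---|---|
| sedentary blocks | log-normal, median 20 min, σ=0.6 | gaps between containers |
| bout duration | log-normal, median 30 s, σ=1.1 | heavy tail gives occasional long walks |
| standing gaps | log-normal, median 30 s, σ=0.75 | within-container interruptions |
| cadence | normal 105 ± 12 steps/min, truncated > 40 | per-bout mean cadence |
| low-opportunity fraction | 0.30, cap 330 s | subjects whose bouts never reach 6 min |
| days per subject | 7 | one observation period |

The low-opportunity mechanism is what reproduces the qualitative
availability pattern of interest — nearly all subjects produce at least
one fully-stepped two-minute window, a clear minority never produce a
six-minute one — without asserting anything about any particular study
population's numbers. All sampling derives from one master seed through
`numpy.random.SeedSequence((seed, subject_index))`, so cohorts are exactly
reproducible and subjects are independent of cohort size. Optional knobs
inject known structure for power studies: spreading observation months
over the year and a cosine month effect on mean cadence, and alternating
sex labels in the manifest.

What the generator does **not** emulate: intra-bout cadence variation,
running (cadence > 150), wear-time gaps and non-wear misclassification,
day-to-day behavioural correlation within a subject, and any biomechanical
signal content. Passing tests therefore demonstrate the correctness of the
segmentation, search and summarisation machinery under controlled
conditions — not the clinical validity of the measure on real monitor
exports.

## Numerical choices and scale

Internally times are float64 seconds since the epoch (sub-microsecond
resolution at 2023 magnitudes); reported window starts are rounded to
nanosecond timestamps. Conservation checks in tests therefore use 1 µs–1 ms
tolerances where sums of thousands of rounded durations are compared;
counts and steps are always integer-exact. The acceptance study uses a
300-subject, 7-day cohort for population measures and 1000 half-hour
streams for oracle equivalence; these sizes give stable proportions (SE
≈ 2–3 percentage points) while keeping a full run around a minute.

## Known limitations

* The measure is sensitive to running: a max window at cadence
  > 150 steps/min likely reflects running opportunity rather than walking
  capacity; cadence is reported so downstream users can flag it.
* Calendar-day splitting is assumed (not wear-time days); windows never
  cross midnight.
* `best_window` availability doubles the per-day search cost and is off by
  default.
* The CSV dialect is this package's own (monitor vendors export
  proprietary formats); a converter is expected upstream.
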