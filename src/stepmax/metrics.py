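"""Day validity, observation selection and population measures.

Pipeline order, per subject:

1. split the event stream into calendar days and run the window sweep on
   each day (:func:`build_day_records`);
2. flag *valid* days — strictly more than 10 h of classified activity and
   strictly more than 500 steps (:func:`flag_valid_days`);
3. keep the first observation period with at least seven valid days
   (:func:`select_observation`) and take per-duration maxima over its valid
   days (:func:`max_over_period`);
4. derive cohort measures: step accumulation rate (peak count / window
   duration), stepping-proportion availability, mean daily count of bouts at
   least as long as the window, distribution shape (skew/kurtosis normality
   rule) and group comparisons.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import core
from .events import EventStream, split_into_days

__all__ = [
    "DayRecord",
    "SubjectSummary",
    "DistributionStats",
    "GroupTestResult",
    "CorrelationResult",
    "VALID_DAY_MIN_HOURS",
    "VALID_DAY_MIN_STEPS",
    "DEFAULT_THRESHOLDS",
    "build_day_records",
    "flag_valid_days",
    "select_observation",
    "max_over_period",
    "stepping_proportion_table",
    "bouts_per_day",
    "distribution_stats",
    "cohort_tests",
    "correlation_between_durations",
    "accumulation_rate_test",
    "summaries_to_frame",
    "summarise_subject",
    "stepping_proportion_from_frame",
]

#: Strict validity thresholds: a valid day has MORE than 10 h classified
#: activity and MORE than 500 steps.
VALID_DAY_MIN_HOURS = 10.0
VALID_DAY_MIN_STEPS = 500

#: Stepping-proportion availability thresholds (fractions of the window).
DEFAULT_THRESHOLDS: tuple[float, ...] = (1.00, 0.95, 0.90, 0.80)


@dataclass(frozen=True)
class DayRecord:
    """One calendar day of one subject, with per-duration window maxima."""

    date: pd.Timestamp
    classified_hours: float
    total_steps: int
    windows: Mapping[float, core.WindowResult]
    bout_durations: np.ndarray = field(repr=False)
    best_stepping: Mapping[float, float] | None = None
    valid: bool = False


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject maxima and derived rates over one selected observation."""

    subject_id: str
    observation_id: int | None
    valid_day_count: int
    max_windows: Mapping[float, core.WindowResult]
    accumulation_rates: Mapping[float, float]
    mean_bouts_per_day: Mapping[float, float]
    month: int | None
    best_stepping: Mapping[float, float] | None = None
    excluded: bool = False
    exclusion_reason: str | None = None


# ---------------------------------------------------------------------- #
# day records


def build_day_records(
    stream: EventStream,
    durations: Sequence[float] = core.DEFAULT_DURATIONS,
    *,
    compute_best_stepping: bool = False,
    min_hours: float = VALID_DAY_MIN_HOURS,
    min_steps: int = VALID_DAY_MIN_STEPS,
) -> list[DayRecord]:
    """Split a stream into days, sweep each day, and flag validity.

    The window search never crosses a day boundary: maxima are per-day, as
    the valid-day rule makes the day the unit of analysis. With
    ``compute_best_stepping`` the per-day maximum counted stepping time per
    duration is also recorded (used by the ``best_window`` availability
    reading).
    """
    records = []
    for day, day_stream in split_into_days(stream):
        windows = core.sweep_window_durations(day_stream, durations)
        bouts = core.merge_strides_to_bouts(day_stream)
        best = None
        if compute_best_stepping:
            best = {
                float(n): core.max_stepping_time_window(day_stream, float(n)).stepping_time
                for n in durations
            }
        records.append(
            DayRecord(
                date=day,
                classified_hours=day_stream.total_duration / 3600.0,
                total_steps=day_stream.total_steps,
                windows=windows,
                bout_durations=np.asarray([b.duration for b in bouts], dtype=float),
                best_stepping=best,
            )
        )
    return flag_valid_days(records, min_hours=min_hours, min_steps=min_steps)


def flag_valid_days(
    days: Sequence[DayRecord],
    *,
    min_hours: float = VALID_DAY_MIN_HOURS,
    min_steps: int = VALID_DAY_MIN_STEPS,
) -> list[DayRecord]:
    """Apply the strict valid-day rule: > ``min_hours`` AND > ``min_steps``.

    Boundary days (exactly 10 h or exactly 500 steps) are invalid. Invalid
    days are retained but excluded from all maxima downstream. Idempotent
    and order-invariant.
    """
    return [
        dataclasses.replace(
            d, valid=(d.classified_hours > min_hours and d.total_steps > min_steps)
        )
        for d in days
    ]


# ---------------------------------------------------------------------- #
# observation selection and period maxima


def max_over_period(days: Sequence[DayRecord], n: float) -> core.WindowResult:
    """Maximum n-second window over the valid days of a period.

    Ties are broken as in the core search: highest count, then shortest
    accumulation time, then earliest day (days are taken in order). With no
    valid days the result is empty: ``window_start`` is ``None`` and the
    count is zero.
    """
    n = float(n)
    best: core.WindowResult | None = None
    for d in days:
        if not d.valid:
            continue
        w = d.windows[n]
        if best is None or (
            w.step_count,
            -w.accumulation_time,
        ) > (best.step_count, -best.accumulation_time):
            best = w
    if best is None:
        return core.WindowResult.zero(n, None)
    return best


def select_observation(
    subject_id: str,
    observations: Sequence[Sequence[DayRecord]],
    *,
    required_days: int = 7,
    durations: Sequence[float] = core.DEFAULT_DURATIONS,
    month: int | None = None,
) -> SubjectSummary:
    """Keep the first observation period with >= ``required_days`` valid days.

    Observations are given in temporal order (typically two, six months
    apart). A subject with no qualifying observation is returned flagged
    ``excluded`` with the reason recorded.
    """
    for obs_id, days in enumerate(observations, start=1):
        valid = [d for d in days if d.valid]
        if len(valid) >= required_days:
            return summarise_period(
                subject_id, days, observation_id=obs_id, durations=durations,
                month=month,
            )
    return SubjectSummary(
        subject_id=subject_id,
        observation_id=None,
        valid_day_count=max(
            (sum(d.valid for d in days) for days in observations), default=0
        ),
        max_windows={},
        accumulation_rates={},
        mean_bouts_per_day={},
        month=month,
        excluded=True,
        exclusion_reason=f"no observation with >={required_days} valid days",
    )


def summarise_period(
    subject_id: str,
    days: Sequence[DayRecord],
    *,
    observation_id: int | None = 1,
    durations: Sequence[float] = core.DEFAULT_DURATIONS,
    month: int | None = None,
) -> SubjectSummary:
    """Build a :class:`SubjectSummary` from one observation period's days."""
    valid = [d for d in days if d.valid]
    maxima = {float(n): max_over_period(days, n) for n in durations}
    rates = {n: w.accumulation_rate for n, w in maxima.items()}
    mbpd = {float(n): bouts_per_day(days, n) for n in durations}
    best = None
    if valid and valid[0].best_stepping is not None:
        best = {
            float(n): max((d.best_stepping[float(n)] for d in valid), default=0.0)
            for n in durations
        }
    if month is None and valid:
        month = int(valid[0].date.month)
    return SubjectSummary(
        subject_id=subject_id,
        observation_id=observation_id,
        valid_day_count=len(valid),
        max_windows=maxima,
        accumulation_rates=rates,
        mean_bouts_per_day=mbpd,
        month=month,
        best_stepping=best,
    )


def bouts_per_day(days: Sequence[DayRecord], n: float) -> float:
    """Mean, over valid days, of the count of bouts with duration >= n.

    The boundary is inclusive: a bout lasting exactly ``n`` seconds counts.
    Returns NaN when there are no valid days.
    """
    counts = [
        int(np.count_nonzero(d.bout_durations >= float(n))) for d in days if d.valid
    ]
    return float(np.mean(counts)) if counts else float("nan")


def summarise_subject(
    subject_id: str,
    observation_streams: Sequence[EventStream],
    *,
    durations: Sequence[float] = core.DEFAULT_DURATIONS,
    required_days: int = 7,
    compute_best_stepping: bool = False,
    month: int | None = None,
) -> tuple[SubjectSummary, list[list[DayRecord]]]:
    """Full per-subject pipeline: day split -> sweep -> validity -> selection.

    ``observation_streams`` are the subject's observation periods in
    temporal order (one stream each). Returns the summary and the per-
    observation day records.
    """
    observations = [
        build_day_records(s, durations, compute_best_stepping=compute_best_stepping)
        for s in observation_streams
    ]
    summary = select_observation(
        subject_id, observations, required_days=required_days,
        durations=durations, month=month,
    )
    return summary, observations


# ---------------------------------------------------------------------- #
# availability


def stepping_proportion_table(
    summaries: Sequence[SubjectSummary],
    *,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    durations: Sequence[float] | None = None,
    mode: str = "max_count_window",
) -> pd.DataFrame:
    """Proportion of subjects whose stepping time filled the window.

    For each window duration ``n`` and each threshold ``q`` in (0, 1], the
    fraction of (non-excluded) subjects whose stepping time within the
    relevant window is at least ``q * n`` seconds.

    mode ``"max_count_window"`` (default) uses the stepping time of the
    window in which the subject accumulated their maximum step count; mode
    ``"best_window"`` uses the maximum stepping time over all windows (the
    summaries must have been built with ``compute_best_stepping=True``).

    Returns a DataFrame indexed by duration (seconds) with one column per
    threshold, values in [0, 1].
    """
    if mode not in ("max_count_window", "best_window"):
        raise ValueError(f"unknown mode {mode!r}")
    included = [s for s in summaries if not s.excluded]
    if not included:
        raise ValueError("empty cohort: no included subjects")
    for q in thresholds:
        if not (0 < q <= 1):
            raise ValueError(f"threshold {q} outside (0, 1]")
    if durations is None:
        durations = sorted(included[0].max_windows.keys())
    rows = {}
    for n in durations:
        n = float(n)
        if mode == "max_count_window":
            times = np.asarray([s.max_windows[n].stepping_time for s in included])
        else:
            if any(s.best_stepping is None for s in included):
                raise ValueError(
                    "best_window mode requires summaries built with "
                    "compute_best_stepping=True"
                )
            times = np.asarray([s.best_stepping[n] for s in included])
        # half-millisecond slack absorbs float round-off at exact coverage
        rows[n] = {
            q: float(np.mean(times >= q * n - 5e-4)) for q in thresholds
        }
    table = pd.DataFrame(rows).T
    table.index.name = "duration_s"
    table.columns.name = "threshold"
    return table


def stepping_proportion_from_frame(
    frame: pd.DataFrame,
    *,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    durations: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Availability table recomputed from a flat summary frame.

    Equivalent to :func:`stepping_proportion_table` in its default mode but
    reads the ``stepping_time_<n>`` columns written by
    :func:`summaries_to_frame`, so a report can be regenerated from summary
    CSVs alone.
    """
    if len(frame) == 0:
        raise ValueError("empty cohort")
    if durations is None:
        durations = sorted(
            float(c.split("_")[-1])
            for c in frame.columns
            if c.startswith("stepping_time_")
        )
    rows = {}
    for n in durations:
        times = frame[f"stepping_time_{int(n)}"].to_numpy(dtype=float)
        rows[float(n)] = {q: float(np.mean(times >= q * n - 5e-4)) for q in thresholds}
    table = pd.DataFrame(rows).T
    table.index.name = "duration_s"
    table.columns.name = "threshold"
    return table


# ---------------------------------------------------------------------- #
# distribution shape


@dataclass(frozen=True)
class DistributionStats:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    skew: float
    kurtosis: float
    is_normal: bool
    degenerate: bool = False


def distribution_stats(values: Sequence[float], *, corrected: bool = True) -> DistributionStats:
    """Sample moments and the skew/kurtosis normality classification.

    ``skew`` is the (by default bias-corrected, adjusted Fisher–Pearson)
    sample skewness and ``kurtosis`` the excess kurtosis; ``corrected=False``
    gives the plain moment ratios g1 and g2. The distribution is classified
    normal when \\|skew\\| < 2 and kurtosis < 7. A constant sample leaves both
    undefined (NaN) and is flagged ``degenerate``.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("distribution_stats requires at least 3 values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return DistributionStats(
            len(x), mean, 0.0, float(x.min()), float(x.max()),
            float("nan"), float("nan"), False, degenerate=True,
        )
    skew = float(sps.skew(x, bias=not corrected))
    kurt = float(sps.kurtosis(x, fisher=True, bias=not corrected))
    return DistributionStats(
        n=len(x),
        mean=mean,
        sd=sd,
        min=float(x.min()),
        max=float(x.max()),
        skew=skew,
        kurtosis=kurt,
        is_normal=bool(abs(skew) < 2 and kurt < 7),
    )


# ---------------------------------------------------------------------- #
# cohort comparisons


@dataclass(frozen=True)
class GroupTestResult:
    test: str  # "t" or "anova"
    statistic: float
    df: tuple[float, ...]
    p_value: float
    groups: tuple


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p_value: float


def summaries_to_frame(
    summaries: Sequence[SubjectSummary],
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flatten summaries to one row per subject.

    Columns: ``max_steps_<n>``, ``rate_<n>``, ``stepping_time_<n>``,
    ``bouts_per_day_<n>`` for each duration, plus ``valid_days`` and
    ``month``. ``metadata`` (indexed by or containing ``subject_id``, e.g.
    the synthetic cohort manifest with a ``sex`` column) is joined in.
    """
    rows = []
    for s in summaries:
        if s.excluded:
            continue
        row: dict = {
            "subject_id": s.subject_id,
            "observation_id": s.observation_id,
            "valid_days": s.valid_day_count,
            "month": s.month,
        }
        for n, w in sorted(s.max_windows.items()):
            key = f"{int(n)}"
            row[f"max_steps_{key}"] = w.step_count
            row[f"rate_{key}"] = s.accumulation_rates[n]
            row[f"stepping_time_{key}"] = w.stepping_time
            row[f"bouts_per_day_{key}"] = s.mean_bouts_per_day[n]
        rows.append(row)
    frame = pd.DataFrame(rows)
    if metadata is not None:
        meta = metadata.reset_index() if metadata.index.name == "subject_id" else metadata
        dupes = (set(meta.columns) & set(frame.columns)) - {"subject_id"}
        frame = frame.merge(meta.drop(columns=list(dupes)), on="subject_id", how="left")
    return frame


def cohort_tests(
    frame: pd.DataFrame,
    grouping: str,
    value: str,
) -> GroupTestResult:
    """Group comparison of one summary column.

    ``grouping="sex"`` runs a two-sample (Welch-free, pooled-variance) t
    test; ``grouping="month"`` a one-way ANOVA across months. Raises
    ``ValueError`` naming any group with fewer than 2 subjects.
    """
    if grouping not in frame.columns:
        raise ValueError(f"grouping column {grouping!r} not in frame")
    groups = []
    labels = []
    for label, chunk in frame.groupby(grouping):
        vals = chunk[value].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 subjects")
        groups.append(vals)
        labels.append(label)
    if grouping == "sex" or len(groups) == 2:
        if len(groups) != 2:
            raise ValueError(f"two-sample test needs exactly 2 groups, got {len(groups)}")
        res = sps.ttest_ind(groups[0], groups[1], equal_var=True)
        df = len(groups[0]) + len(groups[1]) - 2
        return GroupTestResult("t", float(res.statistic), (float(df),),
                               float(res.pvalue), tuple(labels))
    res = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return GroupTestResult("anova", float(res.statistic), (float(df1), float(df2)),
                           float(res.pvalue), tuple(labels))


def correlation_between_durations(
    frame: pd.DataFrame, n_a: float = 120, n_b: float = 360
) -> CorrelationResult:
    """Pearson correlation between per-subject maxima at two durations."""
    a = frame[f"max_steps_{int(n_a)}"].to_numpy(dtype=float)
    b = frame[f"max_steps_{int(n_b)}"].to_numpy(dtype=float)
    if len(a) < 3:
        raise ValueError("correlation requires at least 3 subjects")
    res = sps.pearsonr(a, b)
    return CorrelationResult(float(res.statistic), len(a) - 2, float(res.pvalue))


def accumulation_rate_test(
    frame: pd.DataFrame, n_a: float = 120, n_b: float = 360, *, paired: bool = True
) -> GroupTestResult:
    """Compare per-subject accumulation rates at two durations.

    The rates are paired within subject; ``paired=False`` gives the unpaired
    two-sample variant for comparability with analyses that treat the two
    duration columns as independent samples.
    """
    a = frame[f"rate_{int(n_a)}"].to_numpy(dtype=float)
    b = frame[f"rate_{int(n_b)}"].to_numpy(dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 subjects")
    if paired:
        res = sps.ttest_rel(a, b)
        df = len(a) - 1
    else:
        res = sps.ttest_ind(a, b, equal_var=True)
        df = 2 * len(a) - 2
    return GroupTestResult(
        "t", float(res.statistic), (float(df),), float(res.pvalue),
        (f"rate_{int(n_a)}", f"rate_{int(n_b)}"),
    )
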