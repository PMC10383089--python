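"""Event-format activity data: model, validation, CSV I/O, day splitting.

Thigh-worn activity monitors export free-living records as a sequence of
*events*: each row is one contiguous period of a single activity class
(sedentary = sitting/lying, standing, or a single stride). A stride event
comprises exactly two steps. This module defines the in-memory model
(:class:`ActivityEvent`, :class:`EventStream`), the plain-text CSV dialect
used for interchange, and calendar-day splitting.

CSV dialect (UTF-8, RFC 4180, ISO 8601 timestamps)::

    subject_id,start_iso8601,duration_s,activity,steps
    S0001,2023-03-06T07:00:00.000,3600.0,sedentary,0
    S0001,2023-03-06T08:00:00.000,60.0,standing,0
    S0001,2023-03-06T08:01:00.000,1.2,stride,2

Timestamps are naive local time; the day boundary is midnight local time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Activity",
    "ActivityEvent",
    "EventStream",
    "EventStreamError",
    "ParseError",
    "IntegrityError",
    "read_events",
    "write_events",
    "split_into_days",
    "STEPS_PER_STRIDE",
    "GAP_TOLERANCE",
    "CSV_COLUMNS",
]

STEPS_PER_STRIDE = 2
#: Maximum unexplained gap (seconds) between consecutive events.
GAP_TOLERANCE = 1e-3
CSV_COLUMNS = ["subject_id", "start_iso8601", "duration_s", "activity", "steps"]

_NS = 1e9  # nanoseconds per second


class Activity(str, enum.Enum):
    """Posture/activity class of a single event."""

    SEDENTARY = "sedentary"
    STANDING = "standing"
    STRIDE = "stride"


class EventStreamError(ValueError):
    """Base class for event-stream validation failures."""


class ParseError(EventStreamError):
    """A row of an event file could not be interpreted."""


class IntegrityError(EventStreamError):
    """The event sequence violates a stream invariant (overlap, bad steps...)."""


@dataclass(frozen=True)
class ActivityEvent:
    """One contiguous period of a single activity class.

    Parameters
    ----------
    start : pandas.Timestamp
        Naive local start time.
    duration : float
        Event duration in seconds, strictly positive.
    activity : Activity
        Posture/activity class.
    steps : int
        2 for a stride event, 0 otherwise. (A stride fragment produced by a
        midnight split may carry 0 steps; see :func:`split_into_days`.)
    """

    start: pd.Timestamp
    duration: float
    activity: Activity
    steps: int = 0

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=self.duration)


class EventStream:
    """A validated, time-ordered sequence of events for one subject.

    Backed by a :class:`pandas.DataFrame` with columns ``start``
    (datetime64[ns]), ``duration`` (float seconds), ``activity`` (str) and
    ``steps`` (int); rows are sorted by ``start`` and consecutive events are
    contiguous to within ``gap_tolerance`` seconds, with overlaps forbidden.
    """

    def __init__(
        self,
        subject_id: str,
        frame: pd.DataFrame,
        *,
        gap_tolerance: float = GAP_TOLERANCE,
        validate: bool = True,
    ) -> None:
        if not subject_id:
            raise EventStreamError("subject_id must be non-empty")
        self.subject_id = str(subject_id)
        frame = frame.reset_index(drop=True)
        if list(frame.columns) != ["start", "duration", "activity", "steps"]:
            frame = frame[["start", "duration", "activity", "steps"]]
        self._frame = frame
        self.gap_tolerance = float(gap_tolerance)
        self._cache: dict = {}
        if validate:
            self._validate()

    # ------------------------------------------------------------------ #
    # construction helpers

    @classmethod
    def from_events(
        cls,
        subject_id: str,
        events: Sequence[ActivityEvent],
        *,
        gap_tolerance: float = GAP_TOLERANCE,
        validate: bool = True,
    ) -> "EventStream":
        frame = pd.DataFrame(
            {
                "start": pd.to_datetime([e.start for e in events]),
                "duration": np.asarray([e.duration for e in events], dtype=float),
                "activity": [Activity(e.activity).value for e in events],
                "steps": np.asarray([e.steps for e in events], dtype=np.int64),
            }
        )
        if not events:
            frame = _empty_frame()
        return cls(subject_id, frame, gap_tolerance=gap_tolerance, validate=validate)

    # ------------------------------------------------------------------ #
    # validation

    def _validate(self) -> None:
        f = self._frame
        if len(f) == 0:
            return
        if f["start"].isna().any():
            raise ParseError("missing start timestamp")
        dur = f["duration"].to_numpy(dtype=float)
        if not np.all(dur > 0):
            row = int(np.flatnonzero(~(dur > 0))[0])
            raise IntegrityError(f"non-positive duration at row {row}")
        starts = f["start"].astype("int64").to_numpy() / _NS
        if np.any(np.diff(starts) < 0):
            raise IntegrityError("events are not sorted by start time")
        ends = starts + dur
        gaps = starts[1:] - ends[:-1]
        if len(gaps):
            bad = np.flatnonzero((gaps < -self.gap_tolerance) | (gaps > self.gap_tolerance))
            if len(bad):
                row = int(bad[0]) + 1
                if gaps[bad[0]] < 0:
                    raise IntegrityError(
                        f"events overlap by {-gaps[bad[0]]:.4f} s at row {row}"
                    )
                raise IntegrityError(
                    f"gap of {gaps[bad[0]]:.4f} s before row {row} exceeds "
                    f"gap_tolerance={self.gap_tolerance} s"
                )
        act = f["activity"].to_numpy()
        known = np.isin(act, [a.value for a in Activity])
        if not known.all():
            row = int(np.flatnonzero(~known)[0])
            raise ParseError(f"unknown activity code {act[row]!r} at row {row}")
        steps = f["steps"].to_numpy()
        stride = act == Activity.STRIDE.value
        # stride fragments from a midnight split may carry 0 steps
        if not np.isin(steps[stride], (0, STEPS_PER_STRIDE)).all():
            row = int(np.flatnonzero(stride)[np.flatnonzero(
                ~np.isin(steps[stride], (0, STEPS_PER_STRIDE)))[0]])
            raise IntegrityError(
                f"stride event at row {row} carries {steps[row]} steps; "
                f"a stride comprises exactly {STEPS_PER_STRIDE} steps"
            )
        if np.any(steps[~stride] != 0):
            row = int(np.flatnonzero(~stride)[np.flatnonzero(steps[~stride] != 0)[0]])
            raise IntegrityError(f"non-stride event at row {row} carries steps")

    # ------------------------------------------------------------------ #
    # accessors

    @property
    def frame(self) -> pd.DataFrame:
        """The backing DataFrame (do not mutate)."""
        return self._frame

    @property
    def events(self) -> list[ActivityEvent]:
        return [
            ActivityEvent(row.start, float(row.duration), Activity(row.activity), int(row.steps))
            for row in self._frame.itertuples(index=False)
        ]

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[ActivityEvent]:
        return iter(self.events)

    @property
    def total_steps(self) -> int:
        return int(self._frame["steps"].sum())

    @property
    def total_duration(self) -> float:
        """Sum of event durations, seconds ('classified time')."""
        return float(self._frame["duration"].sum())

    @property
    def start(self) -> pd.Timestamp | None:
        return self._frame["start"].iloc[0] if len(self._frame) else None

    @property
    def end(self) -> pd.Timestamp | None:
        if not len(self._frame):
            return None
        last = self._frame.iloc[-1]
        return last["start"] + pd.Timedelta(seconds=float(last["duration"]))

    def equals(self, other: "EventStream", *, time_tol_s: float = 1e-3) -> bool:
        """Field-for-field equality (timestamps to ``time_tol_s`` seconds)."""
        if self.subject_id != other.subject_id or len(self) != len(other):
            return False
        if len(self) == 0:
            return True
        a, b = self._frame, other._frame
        dt = (a["start"].astype("int64") - b["start"].astype("int64")).abs().max() / _NS
        return (
            dt <= time_tol_s
            and np.allclose(a["duration"], b["duration"], atol=time_tol_s)
            and (a["activity"].to_numpy() == b["activity"].to_numpy()).all()
            and (a["steps"].to_numpy() == b["steps"].to_numpy()).all()
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"EventStream({self.subject_id!r}, {len(self)} events, "
            f"{self.total_steps} steps)"
        )


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": pd.Series([], dtype="datetime64[ns]"),
            "duration": pd.Series([], dtype=float),
            "activity": pd.Series([], dtype=object),
            "steps": pd.Series([], dtype=np.int64),
        }
    )


# ---------------------------------------------------------------------- #
# CSV I/O


def read_events(
    path: str | Path,
    *,
    gap_tolerance: float = GAP_TOLERANCE,
    bridge_gaps_up_to: float | None = None,
) -> EventStream:
    """Read one subject's events from the package CSV dialect.

    Parameters
    ----------
    path : path
        CSV file with columns ``subject_id,start_iso8601,duration_s,activity,steps``.
    gap_tolerance : float
        Maximum tolerated gap/overlap (seconds) between consecutive events.
    bridge_gaps_up_to : float, optional
        If given, a gap larger than ``gap_tolerance`` but at most this many
        seconds is bridged by extending the earlier event (rounding jitter in
        real exports); larger gaps still raise :class:`IntegrityError`.

    Raises
    ------
    ParseError
        Malformed row, missing column or unknown activity code (names the row).
    IntegrityError
        Overlapping events, a gap beyond tolerance, or a stride row whose step
        count is not 2.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype={"subject_id": str, "activity": str})
    missing = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path.name}: missing column(s) {missing}")
    if len(raw) == 0:
        return EventStream(path.stem, _empty_frame(), gap_tolerance=gap_tolerance)

    subjects = raw["subject_id"].unique()
    if len(subjects) != 1:
        raise ParseError(
            f"{path.name}: expected a single subject per file, found {list(subjects)}"
        )

    start = pd.to_datetime(raw["start_iso8601"], format="ISO8601", errors="coerce")
    if start.isna().any():
        row = int(np.flatnonzero(start.isna())[0])
        raise ParseError(f"{path.name}: unparseable timestamp at row {row}")
    duration = pd.to_numeric(raw["duration_s"], errors="coerce")
    if duration.isna().any():
        row = int(np.flatnonzero(duration.isna())[0])
        raise ParseError(f"{path.name}: unparseable duration at row {row}")
    if (duration <= 0).any():
        row = int(np.flatnonzero(duration <= 0)[0])
        raise ParseError(f"{path.name}: non-positive duration at row {row}")
    steps = pd.to_numeric(raw["steps"], errors="coerce")
    if steps.isna().any() or (steps % 1 != 0).any() or (steps < 0).any():
        row = int(np.flatnonzero(steps.isna() | (steps % 1 != 0) | (steps < 0))[0])
        raise ParseError(f"{path.name}: steps must be a non-negative integer (row {row})")

    frame = pd.DataFrame(
        {
            "start": start,
            "duration": duration.astype(float),
            "activity": raw["activity"].str.lower(),
            "steps": steps.astype(np.int64),
        }
    ).sort_values("start", kind="stable")

    # files must carry whole strides; split fragments are an in-memory artefact
    stride = frame["activity"].to_numpy() == Activity.STRIDE.value
    if np.any(frame["steps"].to_numpy()[stride] != STEPS_PER_STRIDE):
        bad = int(np.flatnonzero(stride & (frame["steps"].to_numpy() != STEPS_PER_STRIDE))[0])
        raise IntegrityError(
            f"{path.name}: stride row {bad} carries "
            f"{int(frame['steps'].iloc[bad])} steps (must be {STEPS_PER_STRIDE})"
        )

    if bridge_gaps_up_to is not None:
        frame = _bridge_gaps(frame, gap_tolerance, bridge_gaps_up_to)

    return EventStream(str(subjects[0]), frame, gap_tolerance=gap_tolerance)


def _bridge_gaps(frame: pd.DataFrame, tol: float, max_bridge: float) -> pd.DataFrame:
    starts = frame["start"].astype("int64").to_numpy() / _NS
    dur = frame["duration"].to_numpy(dtype=float).copy()
    gaps = starts[1:] - (starts[:-1] + dur[:-1])
    bridge = (gaps > tol) & (gaps <= max_bridge)
    if bridge.any():
        dur[:-1][bridge] += gaps[bridge]
        frame = frame.copy()
        frame["duration"] = dur
    return frame


def write_events(stream: EventStream, path: str | Path) -> Path:
    """Write a stream to the package CSV dialect; round-trips via read_events."""
    path = Path(path)
    f = stream.frame
    out = pd.DataFrame(
        {
            "subject_id": stream.subject_id,
            "start_iso8601": f["start"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "duration_s": f["duration"].map(lambda d: format(d, ".6f")),
            "activity": f["activity"],
            "steps": f["steps"],
        }
    )
    if len(f) == 0:
        out = pd.DataFrame(columns=CSV_COLUMNS)
    out.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------- #
# day splitting


def split_into_days(stream: EventStream) -> list[tuple[pd.Timestamp, EventStream]]:
    """Split a stream at local-midnight boundaries into per-day streams.

    An event spanning midnight is cut at the boundary; a cut stride's two
    steps go to the fragment containing the stride's temporal midpoint, so
    total duration and total steps are conserved exactly.

    Returns
    -------
    list of (day, EventStream)
        ``day`` is a normalized midnight Timestamp; days are ordered.
    """
    f = stream.frame
    if len(f) == 0:
        return []

    starts = f["start"]
    ends = starts + pd.to_timedelta(f["duration"], unit="s")
    crosses = (ends.dt.normalize() > starts.dt.normalize()).to_numpy()
    if not crosses.any():
        pieces = f
    else:
        rows = []
        for row in f.loc[crosses].itertuples(index=False):
            rows.extend(_cut_at_midnights(row))
        cut = pd.DataFrame(rows, columns=["start", "duration", "activity", "steps"])
        pieces = (
            pd.concat([f.loc[~crosses], cut], ignore_index=True)
            .sort_values("start", kind="stable")
            .reset_index(drop=True)
        )

    day = pieces["start"].dt.normalize()
    out: list[tuple[pd.Timestamp, EventStream]] = []
    for d, chunk in pieces.groupby(day, sort=True):
        out.append(
            (
                d,
                EventStream(
                    stream.subject_id,
                    chunk.reset_index(drop=True),
                    gap_tolerance=stream.gap_tolerance,
                ),
            )
        )
    return out


def _cut_at_midnights(row) -> list[tuple]:
    start = row.start
    duration = float(row.duration)
    end = start + pd.Timedelta(seconds=duration)
    midpoint = start + pd.Timedelta(seconds=duration / 2)
    pieces = []
    cur = start
    while True:
        boundary = (cur.normalize() + pd.Timedelta(days=1))
        if boundary >= end:
            pieces.append((cur, (end - cur).total_seconds(), row.activity))
            break
        pieces.append((cur, (boundary - cur).total_seconds(), row.activity))
        cur = boundary
    # sub-ns overshoot of a boundary can leave a degenerate fragment
    pieces = [p for p in pieces if p[1] > 1e-9]
    if len(pieces) == 1:
        return [(row.start, row.duration, row.activity, row.steps)]
    # steps follow the fragment containing the event midpoint
    out = []
    assigned = False
    for s, d, a in pieces:
        holds_mid = s <= midpoint < s + pd.Timedelta(seconds=d)
        out.append([s, d, a, int(row.steps) if holds_mid and not assigned else 0])
        assigned = assigned or holds_mid
    if row.steps and not assigned:
        out[-1][3] = int(row.steps)
    return [tuple(r) for r in out]
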