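"""Shared fixtures: hand-built streams and a pure-Python reference oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stepmax.events import Activity, ActivityEvent, EventStream

T0 = pd.Timestamp("2023-03-06 08:00:00")


def make_stream(spec, subject_id="S0001", t0=T0):
    """Build a contiguous stream from (activity, duration) items.

    ``spec`` items are ``("sed"|"stand", duration_s)`` or
    ``("strides", n, stride_duration_s)`` which expands to ``n`` stride
    events of 2 steps each.
    """
    events = []
    t = t0
    for item in spec:
        if item[0] == "strides":
            _, n, d = item
            for _ in range(int(n)):
                events.append(ActivityEvent(t, float(d), Activity.STRIDE, 2))
                t += pd.Timedelta(seconds=float(d))
        else:
            kind, dur = item
            act = Activity.SEDENTARY if kind == "sed" else Activity.STANDING
            events.append(ActivityEvent(t, float(dur), act, 0))
            t += pd.Timedelta(seconds=float(dur))
    return EventStream.from_events(subject_id, events)


def reference_max_step_count(stream, n):
    """Exact maximum n-second step count by first principles.

    Pure-Python, event-object based, and algorithmically naive: tries every
    window start at each stride onset and midpoint and counts strides whose
    midpoints fall inside the window before the first sedentary onset.
    Independent of the numpy search path.
    """
    strides = [e for e in stream.events if e.activity is Activity.STRIDE]
    if not strides:
        return 0
    sed_onsets = [e.start for e in stream.events if e.activity is Activity.SEDENTARY]
    mids = [e.start + pd.Timedelta(seconds=e.duration / 2) for e in strides]
    candidates = sorted(set(mids) | {e.start for e in strides})
    best = 0
    width = pd.Timedelta(seconds=n)
    for T in candidates:
        end = T + width
        cut = min((s for s in sed_onsets if T < s < end), default=end)
        upper = min(cut, end)
        count = sum(e.steps for e, m in zip(strides, mids) if T <= m < upper)
        best = max(best, count)
    return best


def placement_interval_width(stream, n, result):
    """Width (s) of the window-start interval realising ``result``'s count.

    Recomputed from the stream's events: the counted strides are those with
    midpoints in the selected window before its first sedentary onset; any
    window containing exactly their midpoints has start in
    ``(m_last - n, m_first]``.
    """
    T = result.window_start
    # the reported start is rounded to ns; allow sub-microsecond slack so the
    # recount matches the float-second arithmetic of the search
    tol = pd.Timedelta(500, "ns")
    end = T + pd.Timedelta(seconds=n)
    sed_onsets = [e.start for e in stream.events if e.activity is Activity.SEDENTARY]
    cut = min((s for s in sed_onsets if T + tol < s < end), default=end)
    upper = min(cut, end)
    mids = [
        e.start + pd.Timedelta(seconds=e.duration / 2)
        for e in stream.events
        if e.activity is Activity.STRIDE
    ]
    counted = [m for m in mids if T - tol <= m < upper]
    if not counted:
        return float(n)
    m_first, m_last = counted[0], counted[-1]
    # feasible starts: (m_last - n, m_first], further bounded below by the
    # last sedentary onset not after m_last (an onset in (T, m_last] would
    # truncate the count before m_last)
    lo = m_last - pd.Timedelta(seconds=n)
    for s in sed_onsets:
        if lo < s <= m_last:
            lo = max(lo, s)
    return (m_first - lo).total_seconds()


@pytest.fixture
def uniform_bout_stream():
    """stand 60 s | 120 strides of 1 s (240 steps, cadence 120) | stand 60 s."""
    return make_stream([("stand", 60), ("strides", 120, 1.0), ("stand", 60)])
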