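"""Synthetic free-living event streams with ground-truth bookkeeping.

The generator emulates the behavioural structure the analysis assumes: each
day is a long overnight sedentary block, then a waking window in which
sedentary blocks alternate with *upright containers*; each container is
quiet standing interleaved with stepping bouts realised as runs of uniform
stride events (2 steps each, duration 120/cadence seconds). Bout durations
are log-normal, cadences truncated-normal, and a configurable fraction of
"low-opportunity" subjects have their bout-duration distribution truncated
below a cap — these subjects never produce long continuous stepping, which
is what makes long-window availability fall off across a cohort.

Everything is driven by a single master seed through
``numpy.random.SeedSequence``; identical (config, subject index) pairs give
byte-identical streams and manifests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import special

from .events import Activity, EventStream

__all__ = ["GeneratorConfig", "generate_subject", "generate_cohort", "CohortManifest"]

_SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic behaviour stream.

    Durations are in seconds unless noted; log-normal distributions are
    parameterised by (mu, sigma) of the underlying normal, so the median is
    ``exp(mu)``.
    """

    seed: int = 0
    days_per_subject: int = 7
    start_date: str = "2023-03-06"
    #: waking window, hours from midnight (start, end)
    wake_start_h: float = 7.0
    wake_end_h: float = 23.0
    #: sedentary-block durations between containers, log-normal (mu, sigma)
    sedentary_lognorm: tuple[float, float] = (math.log(20 * 60), 0.6)
    #: stepping-bout durations, log-normal (mu, sigma)
    bout_lognorm: tuple[float, float] = (math.log(30.0), 1.1)
    #: standing gaps inside a container, log-normal (mu, sigma)
    standing_lognorm: tuple[float, float] = (math.log(30.0), 0.75)
    #: mean number of bouts per container (Poisson); None -> use fixed
    bouts_per_container_mean: float = 1.5
    bouts_per_container_fixed: int | None = None
    #: exactly this many containers per day if set, else fill the wake window
    containers_per_day: int | None = None
    #: cadence, steps/min: normal truncated below at cadence_min
    cadence_mean: float = 105.0
    cadence_sd: float = 12.0
    cadence_min: float = 40.0
    #: fraction of subjects whose bout durations are truncated below a cap
    low_opportunity_fraction: float = 0.3
    low_opportunity_cap_s: float = 330.0
    #: cyclic month effect on a subject's mean cadence (steps/min amplitude)
    month_cadence_amplitude: float = 0.0
    #: distribute subjects' observation months over the year
    spread_months: bool = False

    def validate(self) -> None:
        if self.days_per_subject < 1:
            raise ValueError("days_per_subject must be >= 1")
        if not (0 <= self.wake_start_h < self.wake_end_h <= 24):
            raise ValueError("wake window must satisfy 0 <= start < end <= 24 h")
        if self.cadence_min <= 0:
            raise ValueError("cadence_min must be positive (cadence > 0)")
        if not (0 <= self.low_opportunity_fraction <= 1):
            raise ValueError("low_opportunity_fraction must be in [0, 1]")
        for name in ("sedentary_lognorm", "bout_lognorm", "standing_lognorm"):
            mu, sigma = getattr(self, name)
            if sigma < 0:
                raise ValueError(f"{name}: sigma must be >= 0")


@dataclass
class CohortManifest:
    """Ground truth for a generated cohort."""

    config: dict
    subjects: pd.DataFrame  # subject_id, sex, month, low_opportunity
    bouts: pd.DataFrame     # subject_id, day, start_s, duration_s, steps, cadence

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "config": self.config,
                "subjects": self.subjects.to_dict(orient="records"),
                "bouts": self.bouts.to_dict(orient="records"),
            },
            indent=1,
        )


def _lognormal(rng: np.random.Generator, mu: float, sigma: float,
               cap: float | None = None) -> float:
    """Log-normal draw, optionally truncated above at ``cap`` (inverse CDF)."""
    if cap is None:
        return float(np.exp(rng.normal(mu, sigma)))
    if sigma == 0:
        return min(float(np.exp(mu)), cap)
    z_cap = (math.log(cap) - mu) / sigma
    u = rng.uniform(0.0, special.ndtr(z_cap))
    return float(np.exp(mu + sigma * special.ndtri(u)))


def _cadence(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    if sd == 0:
        return max(mean, lo)
    while True:
        c = rng.normal(mean, sd)
        if c > lo:
            return float(c)


class _DayBuilder:
    """Accumulates contiguous events for one day as flat arrays."""

    def __init__(self) -> None:
        self.start: list[float] = []
        self.dur: list[float] = []
        self.act: list[str] = []
        self.steps: list[int] = []

    def add(self, start: float, dur: float, act: str, steps: int = 0) -> None:
        if dur <= 0:
            return
        # merge adjacent sedentary blocks
        if (
            act == Activity.SEDENTARY.value
            and self.act
            and self.act[-1] == Activity.SEDENTARY.value
        ):
            self.dur[-1] += dur
            return
        self.start.append(start)
        self.dur.append(dur)
        self.act.append(act)
        self.steps.append(steps)


def _sample_container(rng: np.random.Generator, cfg: GeneratorConfig,
                      bout_cap: float | None):
    """Sample a container's composition: list of ('stand', dur) / ('bout', ...)."""
    if cfg.bouts_per_container_fixed is not None:
        n_bouts = cfg.bouts_per_container_fixed
    else:
        n_bouts = int(rng.poisson(cfg.bouts_per_container_mean))
    items: list[tuple] = []
    items.append(("stand", _lognormal(rng, *cfg.standing_lognorm)))
    for _ in range(n_bouts):
        cad = _cadence(rng, cfg.cadence_mean, cfg.cadence_sd, cfg.cadence_min)
        # 2 steps per stride at `cad` steps/min; microsecond grid so emitted
        # event durations equal the bookkept ones exactly
        stride_dur = round(120.0 / cad, 6)
        target = _lognormal(rng, *cfg.bout_lognorm, cap=bout_cap)
        n_strides = max(1, int(round(target / stride_dur)))
        items.append(("bout", n_strides, stride_dur, cad))
        items.append(("stand", _lognormal(rng, *cfg.standing_lognorm)))
    duration = sum(
        it[1] if it[0] == "stand" else it[1] * it[2] for it in items
    )
    return items, duration


def generate_subject(
    config: GeneratorConfig,
    subject_id: str = "S0001",
    subject_index: int = 0,
    *,
    cadence_mean_override: float | None = None,
) -> tuple[EventStream, pd.DataFrame]:
    """Generate one subject's multi-day event stream plus ground truth.

    Returns the stream and a bout manifest DataFrame with columns
    ``subject_id, day, start_s, duration_s, steps, cadence`` where
    ``start_s`` is seconds from the stream's first day at midnight.
    Deterministic in (config.seed, subject_index).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), int(subject_index))))

    low_opp = rng.uniform() < config.low_opportunity_fraction
    bout_cap = config.low_opportunity_cap_s if low_opp else None
    cfg = config
    if cadence_mean_override is not None:
        cfg = replace(config, cadence_mean=cadence_mean_override)

    base = pd.Timestamp(cfg.start_date).normalize()
    builder = _DayBuilder()
    truth_rows = []

    for day in range(cfg.days_per_subject):
        day0 = day * _SECONDS_PER_DAY
        wake_start = day0 + cfg.wake_start_h * 3600.0
        wake_end = day0 + cfg.wake_end_h * 3600.0
        builder.add(day0, wake_start - day0, Activity.SEDENTARY.value)
        t = wake_start

        containers: list[tuple[list, float]] = []
        if cfg.containers_per_day is not None:
            for _ in range(cfg.containers_per_day):
                sed = _lognormal(rng, *cfg.sedentary_lognorm)
                items, cdur = _sample_container(rng, cfg, bout_cap)
                containers.append(([("sed", sed)] + items, cdur + sed))
        else:
            t_fill = t
            while True:
                sed = _lognormal(rng, *cfg.sedentary_lognorm)
                items, cdur = _sample_container(rng, cfg, bout_cap)
                if t_fill + sed + cdur > wake_end:
                    break
                containers.append(([("sed", sed)] + items, cdur + sed))
                t_fill += sed + cdur

        for items, _ in containers:
            for it in items:
                if it[0] == "sed":
                    builder.add(t, it[1], Activity.SEDENTARY.value)
                    t += it[1]
                elif it[0] == "stand":
                    builder.add(t, it[1], Activity.STANDING.value)
                    t += it[1]
                else:
                    _, n_strides, stride_dur, cad = it
                    bout_dur = n_strides * stride_dur
                    if t + bout_dur > (day + 1) * _SECONDS_PER_DAY:
                        raise ValueError(
                            "infeasible config: container content overruns the day"
                        )
                    for k in range(n_strides):
                        builder.add(t + k * stride_dur, stride_dur,
                                    Activity.STRIDE.value, 2)
                    truth_rows.append(
                        {
                            "subject_id": subject_id,
                            "day": day,
                            "start_s": t,
                            "duration_s": bout_dur,
                            "steps": 2 * n_strides,
                            "cadence": 2 * n_strides / (bout_dur / 60.0),
                        }
                    )
                    t += bout_dur
        if t > (day + 1) * _SECONDS_PER_DAY:
            raise ValueError("infeasible config: containers overrun the day")
        builder.add(t, (day + 1) * _SECONDS_PER_DAY - t, Activity.SEDENTARY.value)

    frame = pd.DataFrame(
        {
            "start": base + pd.to_timedelta(np.round(np.asarray(builder.start), 6), unit="s"),
            "duration": np.round(np.asarray(builder.dur, dtype=float), 6),
            "activity": builder.act,
            "steps": np.asarray(builder.steps, dtype=np.int64),
        }
    )
    # re-derive starts from cumulative durations so rounding never opens gaps
    t0 = frame["start"].iloc[0]
    cum = np.concatenate(([0.0], np.cumsum(frame["duration"].to_numpy())[:-1]))
    frame["start"] = t0 + pd.to_timedelta(cum, unit="s")
    # pin the stream end to the final midnight (rounding drift is < ms and
    # always absorbed by the trailing sedentary block)
    total = cfg.days_per_subject * _SECONDS_PER_DAY
    frame.iloc[-1, frame.columns.get_loc("duration")] = total - cum[-1]

    stream = EventStream(subject_id, frame)
    truth = pd.DataFrame(
        truth_rows,
        columns=["subject_id", "day", "start_s", "duration_s", "steps", "cadence"],
    )
    stream._cache["low_opportunity"] = low_opp
    return stream, truth


def generate_cohort(
    config: GeneratorConfig, n_subjects: int
) -> tuple[list[EventStream], CohortManifest]:
    """Generate a cohort of independent subjects from one master seed.

    Subject ``i`` uses sub-seed ``SeedSequence((seed, i))``; sex alternates
    M/F; the observation month is the start month, spread over the year when
    ``config.spread_months`` is set. A non-zero
    ``config.month_cadence_amplitude`` shifts each subject's mean cadence by
    ``A * cos(2*pi*(month - 6)/12)`` (peak in June), which injects a known
    month effect for power studies.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config.validate()
    streams = []
    subject_rows = []
    bout_frames = []
    for i in range(n_subjects):
        sid = f"S{i + 1:04d}"
        cfg = config
        month = pd.Timestamp(config.start_date).month
        if config.spread_months:
            month = (i % 12) + 1
            start = pd.Timestamp(year=2023, month=month, day=3)
            cfg = replace(cfg, start_date=start.strftime("%Y-%m-%d"))
        cad_override = None
        if config.month_cadence_amplitude:
            cad_override = config.cadence_mean + config.month_cadence_amplitude * math.cos(
                2 * math.pi * (month - 6) / 12.0
            )
        stream, truth = generate_subject(
            cfg, sid, subject_index=i, cadence_mean_override=cad_override
        )
        streams.append(stream)
        bout_frames.append(truth)
        subject_rows.append(
            {
                "subject_id": sid,
                "sex": "M" if i % 2 == 0 else "F",
                "month": month,
                "low_opportunity": bool(stream._cache["low_opportunity"]),
            }
        )
    manifest = CohortManifest(
        config={**asdict(config)},
        subjects=pd.DataFrame(subject_rows),
        bouts=pd.concat(bout_frames, ignore_index=True)
        if bout_frames
        else pd.DataFrame(columns=["subject_id", "day", "start_s", "duration_s", "steps", "cadence"]),
    )
    return streams, manifest
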