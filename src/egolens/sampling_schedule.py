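"""Signal-contingent prompt schedules and compliance summaries.

The study design combines two semi-fixed assessment moments (morning
and evening questionnaires, drawn uniformly within their daily windows)
with a number of semi-random daytime prompts per day over a 28-day
period. "Semi-random" is operationalised as block randomisation: the
daytime window is split into ``n_random`` equal blocks, one uniform
draw per block, with a minimum gap between any two same-day prompts.
Gap enforcement first re-samples within the block (which leaves the
uniform-within-block marginal approximately intact) and only then falls
back to a deterministic push-apart clamped to the block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from typing import Optional, Sequence

import numpy as np

from .core_model import InteractionEvent, MomentaryResponse, Prompt

_CET = timezone(timedelta(hours=2))

_MAX_RESAMPLES = 100


class InfeasibleScheduleError(ValueError):
    """The requested prompt density cannot satisfy the minimum gap."""


@dataclass
class ScheduleConfig:
    """Parameters of the daily sampling scheme.

    Defaults reproduce the study design: 28 days, morning and evening
    questionnaires plus 4 semi-random daytime prompts, 30-minute
    minimum gap. Window placements are configuration, not claims about
    the original study (which did not publish them).
    """

    n_days: int = 28
    start_date: date = date(2021, 10, 4)
    tz: timezone = _CET
    morning_window: tuple[time, time] = (time(8, 0), time(10, 0))
    evening_window: tuple[time, time] = (time(20, 0), time(22, 0))
    n_random: int = 4
    random_window: tuple[time, time] = (time(10, 0), time(20, 0))
    min_gap_minutes: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        for lo, hi in (self.morning_window, self.evening_window, self.random_window):
            if lo >= hi:
                raise InfeasibleScheduleError("window start must precede window end")
        if self.n_days < 1:
            raise InfeasibleScheduleError("n_days must be >= 1")
        if self.n_random < 0:
            raise InfeasibleScheduleError("n_random must be >= 0")
        if self.n_random:
            span = _minutes(self.random_window[1]) - _minutes(self.random_window[0])
            if self.n_random * self.min_gap_minutes > span:
                raise InfeasibleScheduleError(
                    f"{self.n_random} prompts with a {self.min_gap_minutes:g}-minute gap "
                    f"do not fit a {span:g}-minute window"
                )


def _minutes(t: time) -> float:
    return t.hour * 60 + t.minute + t.second / 60


def _at(day: date, minutes: float, tz: timezone) -> datetime:
    base = datetime(day.year, day.month, day.day, tzinfo=tz)
    return base + timedelta(minutes=minutes)


def _draw_with_gap(rng, lo: float, hi: float, prev: Optional[float], gap: float) -> float:
    """Uniform draw in [lo, hi] at least ``gap`` after ``prev``."""
    draw = rng.uniform(lo, hi)
    if prev is None or draw >= prev + gap:
        return draw
    for _ in range(_MAX_RESAMPLES):
        draw = rng.uniform(lo, hi)
        if draw >= prev + gap:
            return draw
    # deterministic push-apart, clamped to the window
    pushed = min(hi, max(draw, prev + gap))
    if pushed < prev + gap:
        raise InfeasibleScheduleError("minimum gap cannot be honoured within the window")
    return pushed


def generate_schedule(config: ScheduleConfig) -> list[Prompt]:
    """Generate the full prompt list; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    gap = config.min_gap_minutes
    r_lo, r_hi = (_minutes(t) for t in config.random_window)
    block = (r_hi - r_lo) / config.n_random if config.n_random else 0.0

    prompts: list[Prompt] = []
    for day_idx in range(1, config.n_days + 1):
        day = config.start_date + timedelta(days=day_idx - 1)
        prev: Optional[float] = None
        slots: list[tuple[str, str, float, float]] = [
            ("morning", f"d{day_idx:02d}-morning", *(_minutes(t) for t in config.morning_window))
        ]
        for k in range(config.n_random):
            slots.append(
                ("random", f"d{day_idx:02d}-random{k + 1}", r_lo + k * block, r_lo + (k + 1) * block)
            )
        slots.append(
            ("evening", f"d{day_idx:02d}-evening", *(_minutes(t) for t in config.evening_window))
        )
        for kind, pid, lo, hi in slots:
            minute = _draw_with_gap(rng, lo, hi, prev, gap)
            prev = minute
            prompts.append(
                Prompt(
                    prompt_id=pid,
                    day_index=day_idx,
                    kind=kind,
                    scheduled_time=_at(day, minute, config.tz),
                    window_start=_at(day, lo, config.tz),
                    window_end=_at(day, hi, config.tz),
                )
            )
    return prompts


@dataclass
class WeekCompliance:
    week: int  # 1-based, aligned to study day 1 (days 1-7, 8-14, ...)
    n_scheduled: int
    n_answered: int
    n_events_logged: int

    @property
    def compliance_rate(self) -> float:
        return self.n_answered / self.n_scheduled if self.n_scheduled else 0.0


@dataclass
class ComplianceSummary:
    """Weekly compliance and interaction-log counts.

    Mirrors the weekly participant email: the fraction of scheduled
    prompts answered plus the number of logged interactions. Logged
    interactions are participant-initiated (event-contingent) and are
    therefore counted, never added to the compliance denominator.
    """

    weeks: list[WeekCompliance] = field(default_factory=list)

    @property
    def overall_rate(self) -> float:
        sched = sum(w.n_scheduled for w in self.weeks)
        return sum(w.n_answered for w in self.weeks) / sched if sched else 0.0

    @property
    def n_events_total(self) -> int:
        return sum(w.n_events_logged for w in self.weeks)


def compliance(
    schedule: Sequence[Prompt],
    responses: Sequence[MomentaryResponse],
    events: Sequence[InteractionEvent] = (),
) -> ComplianceSummary:
    """Weekly compliance rates and event counts.

    A prompt counts as answered when a response with a non-missing
    ``response_time`` references it; order of the response list is
    irrelevant. Raises on responses referencing unknown prompts.
    """
    by_id = {p.prompt_id: p for p in schedule}
    if not by_id:
        return ComplianceSummary(weeks=[])
    max_day = max(p.day_index for p in schedule)
    n_weeks = math.ceil(max_day / 7)

    scheduled = [0] * n_weeks
    answered = [0] * n_weeks
    logged = [0] * n_weeks
    for p in schedule:
        scheduled[(p.day_index - 1) // 7] += 1
    for r in responses:
        p = by_id.get(r.prompt_ref)
        if p is None:
            raise KeyError(f"response references unknown prompt {r.prompt_ref!r}")
        if r.answered:
            answered[(p.day_index - 1) // 7] += 1

    day1 = min(p.scheduled_time for p in schedule).date() - timedelta(
        days=min(p.day_index for p in schedule) - 1
    )
    for e in events:
        day = (e.start_time.date() - day1).days + 1
        if 1 <= day <= max_day:
            logged[(day - 1) // 7] += 1

    return ComplianceSummary(
        weeks=[
            WeekCompliance(week=w + 1, n_scheduled=scheduled[w],
                           n_answered=answered[w], n_events_logged=logged[w])
            for w in range(n_weeks)
        ]
    )
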