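"""Pseudo-random prompt scheduling with snooze and response-window semantics.

Prompts are signal-contingent: each day the sampling window (09:00-21:00 by
default) is split into equal-width epochs, one prompt drawn uniformly within
each epoch, and a minimum gap of one hour enforced between consecutive prompts.
A prompt may be snoozed once for five minutes; the window for responding (15
minutes) is always anchored to the initial alarm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ScheduleConfig",
    "AlarmEvent",
    "WeekSchedule",
    "make_day_schedule",
    "make_week_schedule",
    "apply_snooze",
    "classify_response_time",
]

_MAX_REDRAWS = 100


class ScheduleConfig(BaseModel):
    """Sampling-scheme parameters; defaults give 6 prompts/day for 7 days (42)."""

    model_config = ConfigDict(frozen=True)

    window_start: int = Field(default=540, ge=0, lt=1440)  # 09:00
    window_end: int = Field(default=1260, gt=0, le=1440)  # 21:00
    prompts_per_day: int = Field(default=6, ge=1)
    min_gap: int = Field(default=60, ge=0)
    snooze_delay: int = Field(default=5, ge=0)
    response_window: int = Field(default=15, ge=1)
    days: int = Field(default=7, ge=1)

    @model_validator(mode="after")
    def _feasible(self) -> "ScheduleConfig":
        width = self.window_end - self.window_start
        if width < self.prompts_per_day * self.min_gap:
            raise ValueError(
                f"infeasible schedule: window of {width} min cannot hold "
                f"{self.prompts_per_day} prompts {self.min_gap} min apart"
            )
        return self

    @property
    def n_alarms(self) -> int:
        return self.days * self.prompts_per_day


@dataclass(frozen=True)
class AlarmEvent:
    day_index: int  # 1-based
    time: int  # minutes since midnight, initial alarm
    expiry: int  # fixed at time + response_window, never moved by snooze
    snooze_used: bool = False
    reminder_time: int | None = None


@dataclass(frozen=True)
class WeekSchedule:
    config: ScheduleConfig
    alarms: tuple[AlarmEvent, ...] = field(default_factory=tuple)

    def day(self, day_index: int) -> tuple[AlarmEvent, ...]:
        return tuple(a for a in self.alarms if a.day_index == day_index)


def make_day_schedule(rng: np.random.Generator, config: ScheduleConfig) -> list[int]:
    """Draw one day's prompt times (whole minutes since midnight).

    The window is partitioned into ``prompts_per_day`` equal epochs and one
    time drawn uniformly within each.  A draw closer than ``min_gap`` to the
    previous prompt is redrawn (bounded retries), then deterministically
    repaired to the earliest feasible instant.
    """
    width = config.window_end - config.window_start
    epoch = width / config.prompts_per_day
    times: list[int] = []
    for k in range(config.prompts_per_day):
        lo = config.window_start + int(round(k * epoch))
        hi = config.window_start + int(round((k + 1) * epoch))  # exclusive
        t = int(rng.integers(lo, hi))
        if times:
            for _ in range(_MAX_REDRAWS):
                if t - times[-1] >= config.min_gap:
                    break
                t = int(rng.integers(lo, hi))
            else:
                t = times[-1] + config.min_gap
        if t > config.window_end:
            raise ValueError("infeasible schedule: gap repair exceeded the sampling window")
        times.append(t)
    return times


def make_week_schedule(rng: np.random.Generator, config: ScheduleConfig) -> WeekSchedule:
    """Generate the full run of ``days x prompts_per_day`` alarms (42 at defaults)."""
    alarms: list[AlarmEvent] = []
    for day in range(1, config.days + 1):
        for t in make_day_schedule(rng, config):
            alarms.append(AlarmEvent(day_index=day, time=t, expiry=t + config.response_window))
    return WeekSchedule(config=config, alarms=tuple(alarms))


def apply_snooze(alarm: AlarmEvent, snooze_delay: int = 5) -> AlarmEvent:
    """Schedule the single permitted reminder; the expiry stays anchored.

    The reminder sounds ``snooze_delay`` minutes after the initial alarm and
    may fall outside the sampling window.  A second snooze is rejected.
    """
    if alarm.snooze_used:
        raise ValueError("snooze already used for this alarm; only one snooze is permitted")
    return replace(alarm, snooze_used=True, reminder_time=alarm.time + snooze_delay)


def classify_response_time(alarm: AlarmEvent, answered_at: int) -> str:
    """``"on_time"`` iff the entry began within the response window (inclusive)."""
    if answered_at < alarm.time:
        raise ValueError("answered_at precedes the alarm")
    return "on_time" if answered_at <= alarm.expiry else "expired"
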