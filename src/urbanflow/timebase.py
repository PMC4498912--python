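"""Simulation clock: 15-minute iterations, 6 daily periods, 5+2 day weeks.

A day is divided into morning (6:00-12:00), noon (12:00-17:00), evening
rush (17:00-19:00), evening (19:00-22:00) and night (22:00-6:00), with a
morning rush window (7:30-9:30) carved out of the morning.  All intervals
are half-open [start, end).  The run starts Monday 00:00; a model month is
4 weeks = 28 days.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

MINUTES_PER_ITERATION = 15
ITERATIONS_PER_DAY = 24 * 60 // MINUTES_PER_ITERATION  # 96
DAYS_PER_WEEK = 7
WORKING_DAYS = 5
DAYS_PER_MONTH = 28
ITERATIONS_PER_MONTH = ITERATIONS_PER_DAY * DAYS_PER_MONTH  # 2688


class DayPeriod(enum.IntEnum):
    MORNING = 0
    MORNING_RUSH = 1
    NOON = 2
    EVENING_RUSH = 3
    EVENING = 4
    NIGHT = 5


# (start minute, end minute, period); rush precedence applied for morning.
_BASE_WINDOWS = (
    (6 * 60, 12 * 60, DayPeriod.MORNING),
    (12 * 60, 17 * 60, DayPeriod.NOON),
    (17 * 60, 19 * 60, DayPeriod.EVENING_RUSH),
    (19 * 60, 22 * 60, DayPeriod.EVENING),
)
_MORNING_RUSH = (7 * 60 + 30, 9 * 60 + 30)


@dataclass(frozen=True)
class Clock:
    """Iteration counter with calendar views."""

    iteration: int = 0

    def __post_init__(self):
        if self.iteration < 0:
            raise ValueError("iteration must be non-negative")

    @property
    def day(self) -> int:
        return self.iteration // ITERATIONS_PER_DAY

    @property
    def day_of_week(self) -> int:
        return self.day % DAYS_PER_WEEK

    @property
    def minute_of_day(self) -> int:
        return (self.iteration % ITERATIONS_PER_DAY) * MINUTES_PER_ITERATION

    @property
    def hour(self) -> float:
        return self.minute_of_day / 60.0

    def tick(self) -> "Clock":
        return Clock(self.iteration + 1)


def period_of_minute(minute: int) -> DayPeriod:
    """Effective period containing a minute of the day (rush has precedence)."""
    if _MORNING_RUSH[0] <= minute < _MORNING_RUSH[1]:
        return DayPeriod.MORNING_RUSH
    for start, end, period in _BASE_WINDOWS:
        if start <= minute < end:
            return period
    return DayPeriod.NIGHT


def period_of(clock: Clock) -> DayPeriod:
    """Period containing the iteration's start time."""
    return period_of_minute(clock.minute_of_day)


def is_weekday(clock: Clock) -> bool:
    """Days 0-4 of every week are working days; 5-6 are the weekend."""
    return clock.day_of_week < WORKING_DAYS
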