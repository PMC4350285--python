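"""Months-before-death coordinate system.

All end-of-life windows use constructed 30-day "months" counted
backwards from, and including, the day of death: month 1 is days 0-29
before death, month 2 days 30-59, and so on.  The default 6-month
observation window therefore spans exactly 180 distinct calendar days,
the last of which is the day of death.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

__all__ = ["WindowError", "month_index", "days_before_death", "ObservationWindow"]

DAYS_PER_MONTH = 30


class WindowError(ValueError):
    """Event dated after death, or an otherwise impossible window."""


def days_before_death(event_date: date, death_date: date) -> int:
    """Whole days between event and death; 0 on the day of death."""
    delta = (death_date - event_date).days
    if delta < 0:
        raise WindowError(
            f"event date {event_date.isoformat()} is after death {death_date.isoformat()}"
        )
    return delta


def month_index(event_date: date, death_date: date) -> int:
    """Constructed month in which the event falls (death day -> 1)."""
    return days_before_death(event_date, death_date) // DAYS_PER_MONTH + 1


@dataclass(frozen=True)
class ObservationWindow:
    """A backwards window of ``n_months`` constructed months ending at death.

    The window covers calendar dates ``death_date - (30*n_months - 1)``
    through ``death_date`` inclusive.
    """

    death_date: date
    n_months: int = 6

    def __post_init__(self) -> None:
        if self.n_months < 1:
            raise WindowError(f"n_months must be positive, got {self.n_months}")

    @property
    def n_days(self) -> int:
        return DAYS_PER_MONTH * self.n_months

    @property
    def start_date(self) -> date:
        return self.death_date - timedelta(days=self.n_days - 1)

    def __contains__(self, event_date: date) -> bool:
        return self.start_date <= event_date <= self.death_date

    def month_of(self, event_date: date) -> int:
        """Month index of an in-window event (1 = closest to death)."""
        m = month_index(event_date, self.death_date)
        if m > self.n_months:
            raise WindowError(
                f"{event_date.isoformat()} lies outside the {self.n_months}-month window"
            )
        return m

    def observed_days(self, start: date, end: date) -> int:
        """Number of calendar days of [start, end] that fall in the window."""
        lo = max(start, self.start_date)
        hi = min(end, self.death_date)
        return max(0, (hi - lo).days + 1)
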