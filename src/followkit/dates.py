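"""Imprecise calendar dates and their deterministic resolution.

Follow-up information collected retrospectively often lacks a full date:
a relapse may be known only as "Oct. 2008" or "2007".  Such values are
modelled as an :class:`ImpreciseDate` carrying a year, an optional month
and an optional day, together with an explicit precision.  For analysis the
value is resolved to a single calendar date by the midpoint convention:
month precision resolves to the 15th, year precision to July 1.  The
midpoint minimises the maximum resolution error and keeps resolution
symmetric and deterministic.

Serialization uses ISO 8601 truncated forms (``YYYY``, ``YYYY-MM``,
``YYYY-MM-DD``); precision is inferred from the string length.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from enum import Enum


class DatePrecision(str, Enum):
    DAY = "day"
    MONTH = "month"
    YEAR = "year"


_ISO_RE = re.compile(r"^(\d{4})(?:-(\d{2})(?:-(\d{2}))?)?$")

#: Average Gregorian year length used to convert day counts to years.
DAYS_PER_YEAR = 365.25


class DateError(ValueError):
    """Invalid imprecise-date component combination or unparsable string."""


@dataclass(frozen=True, order=False)
class ImpreciseDate:
    """A calendar date known to day, month or year precision.

    Invariants: ``day`` present implies ``month`` present, and the
    components must denote a valid calendar date (checked on construction
    via the resolved value).
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise DateError(f"day={self.day} given without a month")
        if not 1 <= self.year <= 9999:
            raise DateError(f"year {self.year} out of range")
        if self.month is not None and not 1 <= self.month <= 12:
            raise DateError(f"month {self.month} out of range 1-12")
        # Validates day-of-month (e.g. rejects Feb 30).
        self.resolve()

    @property
    def precision(self) -> DatePrecision:
        if self.day is not None:
            return DatePrecision.DAY
        if self.month is not None:
            return DatePrecision.MONTH
        return DatePrecision.YEAR

    def resolve(self) -> dt.date:
        """Resolve to a single calendar date by the midpoint convention.

        Day precision returns the date itself, month precision the 15th of
        the month, year precision July 1.  Resolution is deterministic.
        """
        if self.day is not None:
            try:
                return dt.date(self.year, self.month, self.day)
            except ValueError as exc:
                raise DateError(str(exc)) from None
        if self.month is not None:
            return dt.date(self.year, self.month, 15)
        return dt.date(self.year, 7, 1)

    def earliest(self) -> dt.date:
        """Earliest calendar date consistent with the stated precision."""
        if self.day is not None:
            return self.resolve()
        if self.month is not None:
            return dt.date(self.year, self.month, 1)
        return dt.date(self.year, 1, 1)

    def latest(self) -> dt.date:
        """Latest calendar date consistent with the stated precision."""
        if self.day is not None:
            return self.resolve()
        if self.month is not None:
            if self.month == 12:
                return dt.date(self.year, 12, 31)
            return dt.date(self.year, self.month + 1, 1) - dt.timedelta(days=1)
        return dt.date(self.year, 12, 31)

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()

    @classmethod
    def parse(cls, text: str) -> "ImpreciseDate":
        """Parse an ISO 8601 truncated form; precision follows the length."""
        m = _ISO_RE.match(text.strip())
        if m is None:
            raise DateError(f"not an ISO 8601 (truncated) date: {text!r}")
        year, month, day = m.groups()
        return cls(
            year=int(year),
            month=int(month) if month is not None else None,
            day=int(day) if day is not None else None,
        )

    @classmethod
    def from_date(cls, d: dt.date) -> "ImpreciseDate":
        return cls(d.year, d.month, d.day)


def resolve_date(d: ImpreciseDate) -> dt.date:
    """Functional alias for :meth:`ImpreciseDate.resolve`."""
    return d.resolve()


def years_between(start: dt.date, end: dt.date) -> float:
    """Duration in years between two dates, using 365.25 days per year."""
    return (end - start).days / DAYS_PER_YEAR
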