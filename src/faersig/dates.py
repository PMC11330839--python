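"""Partial calendar dates as they appear in spontaneous-report databases.

FAERS date fields (``FDA_DT``, ``EVENT_DT``, ``START_DT`` ...) are digit
strings of length 4, 6 or 8: a bare year, a year-month, or a full date.
Downstream analyses care about the precision — time-to-onset arithmetic is
only meaningful between two full dates — so the parsed value carries its
precision explicitly instead of silently padding.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from enum import Enum


class DateParseError(ValueError):
    """Raised for a non-blank date string that is not a valid partial date."""


class Precision(str, Enum):
    YEAR = "year"
    MONTH = "month"
    DAY = "day"


@dataclass(frozen=True, slots=True)
class PartialDate:
    """A calendar date known to year, month or day precision.

    Invariants enforced at construction: a day requires a month, the
    month is in 1..12, and a full date must be a real calendar date
    (leap years included).
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.year <= 9999:
            raise DateParseError(f"year out of range: {self.year}")
        if self.day is not None and self.month is None:
            raise DateParseError("day given without month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise DateParseError(f"month out of range: {self.month}")
        if self.day is not None:
            try:
                _dt.date(self.year, self.month, self.day)  # type: ignore[arg-type]
            except ValueError as exc:
                raise DateParseError(str(exc)) from exc

    @property
    def precision(self) -> Precision:
        if self.day is not None:
            return Precision.DAY
        if self.month is not None:
            return Precision.MONTH
        return Precision.YEAR

    def to_date(self) -> _dt.date:
        """The exact calendar date; only defined at day precision."""
        if self.precision is not Precision.DAY:
            raise ValueError(f"not a day-precision date: {self}")
        return _dt.date(self.year, self.month, self.day)  # type: ignore[arg-type]

    def sort_key(self) -> tuple[int, int, int]:
        """Total-order key padding missing components with 01.

        Used only to order report versions; never for date arithmetic.
        """
        return (self.year, self.month or 1, self.day or 1)

    def compact(self) -> str:
        """Format back to the FAERS digit-string form (YYYY/YYYYMM/YYYYMMDD)."""
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.compact()


def parse_partial_date(raw: str | None) -> PartialDate | None:
    """Parse a FAERS date string; ``None`` for blank, raise for malformed.

    4 digits -> year precision, 6 -> month, 8 -> day.  Anything else
    (wrong length, non-digits, month 00/13, day invalid for its month)
    raises :class:`DateParseError`; the caller decides whether that means
    exclusion or a hard failure.
    """
    if raw is None:
        return None
    s = raw.strip()
    if not s:
        return None
    if not s.isdigit() or len(s) not in (4, 6, 8):
        raise DateParseError(f"not a YYYY[MM[DD]] digit string: {raw!r}")
    year = int(s[:4])
    month = int(s[4:6]) if len(s) >= 6 else None
    day = int(s[6:8]) if len(s) == 8 else None
    return PartialDate(year, month, day)


def pad_compact(raw: str) -> str:
    """Pad a raw date string to 8 characters for ordering only.

    ``"2014"`` -> ``"20140101"``; already-full or malformed strings are
    returned stripped but otherwise untouched, which keeps the ordering
    deterministic even for dirty input.
    """
    s = raw.strip() if raw else ""
    if len(s) == 4:
        return s + "0101"
    if len(s) == 6:
        return s + "01"
    return s
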