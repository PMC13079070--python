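"""Partial calendar dates as they occur in spontaneous-report exports.

Dashboard exports mix day-precision dates ("2016-05-17", "05/17/2016"),
year-month ("2016-05") and bare years ("2016"). Rather than coercing
everything to a day (which silently fabricates precision), dates are kept
with their native precision and each consumer states the precision it
needs: study-window filtering accepts year precision, time-to-onset
arithmetic requires day precision.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from typing import Optional

_MONTH_ABBR = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}


@dataclass(frozen=True, order=True)
class PartialDate:
    """A calendar date known to day, month or year precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day precision requires a month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # validates day-of-month, including leap years
            dt.date(self.year, self.month, self.day)

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def to_date(self) -> dt.date:
        """Exact date; only valid at day precision."""
        if self.precision != "day":
            raise ValueError(f"not day-precise: {self!r}")
        return dt.date(self.year, self.month, self.day)

    def floor_date(self) -> dt.date:
        """Earliest day compatible with this partial date (Jan 1 / 1st)."""
        return dt.date(self.year, self.month or 1, self.day or 1)

    def __str__(self) -> str:
        if self.precision == "day":
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.precision == "month":
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"


def parse_partial_date(raw: object) -> Optional[PartialDate]:
    """Parse a raw date cell; unparseable values become None, never an error."""
    if raw is None:
        return None
    if isinstance(raw, PartialDate):
        return raw
    if isinstance(raw, dt.date):
        return PartialDate(raw.year, raw.month, raw.day)
    text = str(raw).strip()
    if not text or text.lower() in {"nan", "na", "none", "unknown"}:
        return None
    try:
        # ISO-style: 2016, 2016-05, 2016-05-17, 20160517, 201605
        m = re.fullmatch(r"(\d{4})(?:[-/]?(\d{2})(?:[-/]?(\d{2}))?)?", text)
        if m:
            y, mo, d = m.group(1), m.group(2), m.group(3)
            return PartialDate(int(y), int(mo) if mo else None, int(d) if d else None)
        # US dashboard style: 05/17/2016
        m = re.fullmatch(r"(\d{1,2})/(\d{1,2})/(\d{4})", text)
        if m:
            return PartialDate(int(m.group(3)), int(m.group(1)), int(m.group(2)))
        # 17-May-2016 / May-2016
        m = re.fullmatch(r"(?:(\d{1,2})-)?([A-Za-z]{3})[a-z]*-(\d{4})", text)
        if m and m.group(2).lower() in _MONTH_ABBR:
            mo = _MONTH_ABBR[m.group(2).lower()]
            d = int(m.group(1)) if m.group(1) else None
            return PartialDate(int(m.group(3)), mo, d)
    except ValueError:
        return None
    return None
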