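"""Small shared helpers."""

from __future__ import annotations

import math

#: Months are counted from January 2000 (month 0).
EPOCH_YEAR = 2000

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding, which does not match
    how percentages are conventionally reported.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def month_index(iso_date: str) -> int:
    """Convert an ISO-8601 date (``YYYY-MM-DD`` or ``YYYY-MM``) to an integer
    month offset from January 2000. Day-of-month is discarded."""
    parts = str(iso_date).strip().split("-")
    if len(parts) < 2:
        raise ValueError(f"not an ISO date: {iso_date!r}")
    year, month = int(parts[0]), int(parts[1])
    if not 1 <= month <= 12:
        raise ValueError(f"bad month in date: {iso_date!r}")
    return (year - EPOCH_YEAR) * 12 + (month - 1)


def month_to_iso(m: int) -> str:
    """Inverse of :func:`month_index` (first of the month)."""
    year, month = divmod(int(m), 12)
    return f"{EPOCH_YEAR + year:04d}-{month + 1:02d}-01"


def parse_bool(value: str) -> bool | None:
    """Parse a CSV boolean cell; empty string means missing."""
    s = str(value).strip().lower()
    if s == "" or s == "nan":
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"not a boolean: {value!r}")


def fmt_bool(value: bool | None) -> str:
    if value is None:
        return ""
    return "true" if value else "false"
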