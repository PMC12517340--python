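"""Calendar-date parsing for spontaneous-report dumps.

JADER encodes dates as ``YYYYMMDD``, ``YYYYMM`` or ``YYYY``; FAERS uses the
same compact forms, and fixtures may use ISO-8601 ``YYYY-MM-DD``.  Dates
missing the day (or month) are *partial*: they are kept for provenance but
excluded from time-to-onset arithmetic rather than imputed.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass

__all__ = ["ParsedDate", "parse_date"]

_ISO_RE = re.compile(r"^(\d{4})-(\d{2})(?:-(\d{2}))?$")
_COMPACT_RE = re.compile(r"^(\d{4})(\d{2})?(\d{2})?$")


@dataclass(frozen=True)
class ParsedDate:
    """A calendar date with explicit precision.

    ``precision`` is one of ``"day"``, ``"month"``, ``"year"`` or
    ``"missing"``.  ``date`` is a :class:`datetime.date` only when the
    precision is ``"day"``; otherwise ``None``.
    """

    raw: str
    precision: str
    date: _dt.date | None = None

    @property
    def is_full(self) -> bool:
        return self.precision == "day"

    @property
    def is_partial(self) -> bool:
        return self.precision in ("month", "year")

    @property
    def is_missing(self) -> bool:
        return self.precision == "missing"


_MISSING = ParsedDate(raw="", precision="missing")


def parse_date(value: object) -> ParsedDate:
    """Parse a raw date cell into a :class:`ParsedDate`.

    Accepts ISO-8601 (``2020-01-31``, ``2020-01``), JADER/FAERS compact
    (``20200131``, ``202001``, ``2020``), empty strings, and NaN.  Anything
    unparseable is treated as missing (the loaders count such rows in the
    load report rather than failing).
    """
    if value is None:
        return _MISSING
    if isinstance(value, float):
        if value != value:  # NaN
            return _MISSING
        value = int(value)
    s = str(value).strip()
    if not s or s.lower() in ("nan", "none", "nat"):
        return _MISSING

    m = _ISO_RE.match(s) or _COMPACT_RE.match(s)
    if m is None:
        return _MISSING
    year, month, day = m.group(1), m.group(2), m.group(3)
    try:
        if day is not None:
            return ParsedDate(raw=s, precision="day", date=_dt.date(int(year), int(month), int(day)))
        if month is not None:
            _dt.date(int(year), int(month), 1)  # validate month
            return ParsedDate(raw=s, precision="month")
        _dt.date(int(year), 1, 1)
        return ParsedDate(raw=s, precision="year")
    except ValueError:
        return _MISSING
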