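"""Calendar handling.

All dates are integer day offsets from a fixed epoch internally — every
algorithm window in this domain is pure day arithmetic — and are serialized
as ISO-8601 calendar dates.
"""

from __future__ import annotations

import datetime as _dt

EPOCH = _dt.date(2010, 1, 1)

#: days in five years, used for the VTE-history lookback
DAYS_5Y = 1826


def day_to_iso(day: int) -> str:
    """Convert an internal day offset to an ISO-8601 date string."""
    return (EPOCH + _dt.timedelta(days=int(day))).isoformat()


def iso_to_day(text: str) -> int:
    """Parse an ISO-8601 date string to an internal day offset.

    Raises ``ValueError`` on malformed input (propagated with file/row
    context by the I/O layer).
    """
    return (_dt.date.fromisoformat(text) - EPOCH).days
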