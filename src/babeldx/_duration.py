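"""Minimal ISO-8601 duration handling.

Ages and onsets travel through the pipeline as raw ISO-8601 duration
strings (e.g. ``P14Y2M``, ``P3M``, ``P21D``) and are interpreted only at
prompt-rendering time, so no lossy unit conversion ever happens upstream.
Only the date part (Y/M/W/D) plus an optional time part is accepted;
negative components are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_ISO_RE = re.compile(
    r"^P"
    r"(?:(?P<years>\d+)Y)?"
    r"(?:(?P<months>\d+)M)?"
    r"(?:(?P<weeks>\d+)W)?"
    r"(?:(?P<days>\d+)D)?"
    r"(?:T"
    r"(?:(?P<hours>\d+)H)?"
    r"(?:(?P<minutes>\d+)M)?"
    r"(?:(?P<seconds>\d+(?:\.\d+)?)S)?"
    r")?$"
)


@dataclass(frozen=True)
class Duration:
    years: int = 0
    months: int = 0
    weeks: int = 0
    days: int = 0

    def total_days_approx(self) -> float:
        """Approximate length in days (365.25/30.44-day conventions).

        Used only to pick a rendering granularity, never for arithmetic
        that ends up in reported numbers.
        """
        return (
            self.years * 365.25
            + self.months * 30.44
            + self.weeks * 7
            + self.days
        )


def parse_duration(text: str) -> Duration:
    """Parse an ISO-8601 duration string into date components.

    Raises ValueError when the string is not a valid non-negative
    ISO-8601 duration, or designates nothing at all (bare ``P``).
    """
    m = _ISO_RE.match(text)
    if m is None:
        raise ValueError(f"not an ISO-8601 duration: {text!r}")
    parts = m.groupdict()
    if all(v is None for v in parts.values()):
        raise ValueError(f"empty ISO-8601 duration: {text!r}")
    return Duration(
        years=int(parts["years"] or 0),
        months=int(parts["months"] or 0),
        weeks=int(parts["weeks"] or 0),
        days=int(parts["days"] or 0),
    )


def is_valid_duration(text: str) -> bool:
    try:
        parse_duration(text)
    except ValueError:
        return False
    return True
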