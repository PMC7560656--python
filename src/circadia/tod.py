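"""Time-of-diagnosis (TOD) interval parsing.

Self-reported diagnosis statements often date the diagnosis only relatively
("2 weeks ago", "last month", "in 2014", "recently").  This module converts
such phrases into calendar intervals in which the diagnosis most likely
occurred, and intersects multiple statements from the same user; when the
intersection is empty, no TOD is assigned.

Positioning convention for "N units ago" with a unit longer than a day: the
interval is the unit-length span *ending the day before* ``post_date − N
units`` — e.g. "2 weeks ago" posted on 2018-03-15 yields 2018-02-22 to
2018-02-28, the entire week that took place two weeks before the statement.
Day-resolution phrases ("today", "yesterday", "N days ago") denote the single
day ``post_date − N``.  "recently" is read as the 3 months ending at the post
date.  Month and year offsets are calendar offsets with day-of-month clamping
(Mar 31 minus 1 month is Feb 28/29).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from dateutil.relativedelta import relativedelta

__all__ = [
    "DiagnosisInterval",
    "parse_tod",
    "intersect_intervals",
    "load_rules",
    "user_diagnosis_interval",
]


@dataclass(frozen=True)
class DiagnosisInterval:
    """Closed calendar interval [start, end] in which a diagnosis occurred."""

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} after end {self.end}")

    @property
    def days(self) -> int:
        return (self.end - self.start).days + 1


_NUMBER_WORDS = {
    "a": 1, "an": 1, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "a couple of": 2, "couple of": 2, "a few": 3, "few": 3,
    "several": 3,
}
_NUM_ALT = "|".join(re.escape(w) for w in sorted(_NUMBER_WORDS, key=len, reverse=True))

_AGO_RE = re.compile(
    rf"\b(?:(\d+)|({_NUM_ALT}))\s+(day|week|month|year)s?\s+ago\b"
)
_LAST_RE = re.compile(r"\blast\s+(week|month|year)\b")
_IN_YEAR_RE = re.compile(r"\bin\s+((?:19|20)\d{2})\b")
_TODAY_RE = re.compile(r"\btoday\b")
_YESTERDAY_RE = re.compile(r"\byesterday\b")
_RECENTLY_RE = re.compile(r"\brecently\b")

_UNIT_DELTA = {
    "day": lambda n: relativedelta(days=n),
    "week": lambda n: relativedelta(weeks=n),
    "month": lambda n: relativedelta(months=n),
    "year": lambda n: relativedelta(years=n),
}


def _units_ago(n: int, unit: str, post_date: date) -> DiagnosisInterval:
    if unit == "day":
        day = post_date - timedelta(days=n)
        return DiagnosisInterval(day, day)
    end = post_date - _UNIT_DELTA[unit](n) - timedelta(days=1)
    start = post_date - _UNIT_DELTA[unit](n + 1)
    return DiagnosisInterval(start, min(end, post_date))


def load_rules(path) -> Dict[str, Dict]:
    """Load an extra phrase → rule table from JSON.

    Each entry maps a literal phrase (matched case-insensitively on word
    boundaries) to ``{"n": int, "unit": "day|week|month|year"}``, positioned
    by the same convention as "N units ago".  This lets a fuller conversion
    list override or extend the built-in grammar.
    """
    with open(path, encoding="utf-8") as fh:
        rules = json.load(fh)
    for phrase, rule in rules.items():
        if rule.get("unit") not in _UNIT_DELTA or not isinstance(rule.get("n"), int):
            raise ValueError(f"bad rule for phrase {phrase!r}: {rule}")
    return rules


def parse_tod(
    text: str,
    post_date: date,
    extra_rules: Optional[Mapping[str, Mapping]] = None,
) -> Optional[DiagnosisInterval]:
    """Parse a relative time expression into a diagnosis interval.

    Recognizes "N unit(s) ago" (digits or small number words), "today",
    "yesterday", "last week/month/year", "in YYYY" and "recently" (the 3
    months ending at the post date).  Returns ``None`` for text with no
    recognized expression.  Parsed intervals never extend past ``post_date``.
    """
    low = text.lower()

    if extra_rules:
        for phrase in sorted(extra_rules, key=len, reverse=True):
            if re.search(rf"\b{re.escape(phrase.lower())}\b", low):
                rule = extra_rules[phrase]
                return _units_ago(int(rule["n"]), rule["unit"], post_date)

    m = _AGO_RE.search(low)
    if m:
        n = int(m.group(1)) if m.group(1) else _NUMBER_WORDS[m.group(2)]
        return _units_ago(n, m.group(3), post_date)
    if _TODAY_RE.search(low):
        return DiagnosisInterval(post_date, post_date)
    if _YESTERDAY_RE.search(low):
        day = post_date - timedelta(days=1)
        return DiagnosisInterval(day, day)
    m = _LAST_RE.search(low)
    if m:
        return _units_ago(1, m.group(1), post_date)
    m = _IN_YEAR_RE.search(low)
    if m:
        year = int(m.group(1))
        start, end = date(year, 1, 1), date(year, 12, 31)
        if start > post_date:
            return None  # a future year is not a diagnosis date
        return DiagnosisInterval(start, min(end, post_date))
    if _RECENTLY_RE.search(low):
        return DiagnosisInterval(post_date - relativedelta(months=3), post_date)
    return None


def intersect_intervals(
    intervals: Sequence[DiagnosisInterval],
) -> Optional[DiagnosisInterval]:
    """Intersection of closed intervals, or None when it is empty.

    Commutative, associative and idempotent; an empty input list is a usage
    error (there is nothing to intersect).
    """
    if not intervals:
        raise ValueError("intersect_intervals requires a nonempty list")
    start = max(iv.start for iv in intervals)
    end = min(iv.end for iv in intervals)
    if start > end:
        return None
    return DiagnosisInterval(start, end)


def user_diagnosis_interval(
    statements: Iterable[tuple],
    extra_rules: Optional[Mapping[str, Mapping]] = None,
) -> Optional[DiagnosisInterval]:
    """Intersect the parsed intervals of all of a user's dated statements.

    ``statements`` yields ``(text, post_date)`` pairs.  Statements with no
    recognizable time expression are ignored; returns None when no statement
    parses or the parsed intervals are disjoint.
    """
    parsed: List[DiagnosisInterval] = []
    for text, post_date in statements:
        interval = parse_tod(text, post_date, extra_rules)
        if interval is not None:
            parsed.append(interval)
    if not parsed:
        return None
    return intersect_intervals(parsed)
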