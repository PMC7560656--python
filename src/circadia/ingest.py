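"""Cohort ingestion: reading event/profile records, study filters, timezone
localization, and creation-month-matched control sampling.

The filtering rules mirror a cohort-construction funnel for two-cohort
activity studies on microblog data: retweets are excluded (their text is not
authored by the posting user), non-English posts are excluded by the record's
language tag, posts matching the diagnosis search pattern are excluded so the
sample-selection text does not bias downstream content analysis, and users
whose timezone cannot be resolved are dropped because activity must be binned
by local wall-clock hour.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone, tzinfo
from typing import Dict, Iterable, List, Optional, Sequence, Tuple
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .exceptions import FormatError, LocalizationError, MatchingError

__all__ = [
    "EventRecord",
    "UserProfile",
    "FilterReport",
    "read_events",
    "read_profiles",
    "matches_diagnosis_pattern",
    "filter_events",
    "resolve_timezone",
    "localize_hour",
    "localize_hours",
    "matched_sample",
]

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["tweet_id", "user_id", "created_at", "text", "is_retweet", "lang"]
PROFILE_COLUMNS = ["user_id", "timezone", "created_month", "cohort"]


@dataclass(frozen=True)
class EventRecord:
    """One posted message with a timezone-aware UTC timestamp."""

    tweet_id: str
    user_id: str
    created_at_utc: datetime
    text: str
    is_retweet: bool
    lang: str

    def __post_init__(self) -> None:
        if self.created_at_utc.tzinfo is None:
            raise FormatError(f"tweet {self.tweet_id}: naive timestamp")


@dataclass(frozen=True)
class UserProfile:
    """Timezone, account-creation month and cohort label for one user."""

    user_id: str
    timezone: str
    created_month: str
    cohort: Optional[str] = None


@dataclass
class FilterReport:
    """Counts of records removed per filtering rule, plus retained.

    ``malformed`` counts rows rejected while reading; the remaining fields
    partition the filter input, so removed + retained equals the input count.
    """

    malformed: int = 0
    retweet: int = 0
    non_english: int = 0
    diagnosis: int = 0
    unknown_user: int = 0
    no_timezone: int = 0
    retained: int = 0

    @property
    def removed(self) -> int:
        return (
            self.retweet
            + self.non_english
            + self.diagnosis
            + self.unknown_user
            + self.no_timezone
        )

    def to_dict(self) -> Dict[str, int]:
        return {
            "malformed": self.malformed,
            "retweet": self.retweet,
            "non_english": self.non_english,
            "diagnosis": self.diagnosis,
            "unknown_user": self.unknown_user,
            "no_timezone": self.no_timezone,
            "retained": self.retained,
        }


# Word boundary = transition from non-letter to letter, so "9diagnosed"
# still counts but "prediagnosis" does not.
_DIAGNOSIS_RE = re.compile(r"(?<![a-z])diagnos")
_DEPRESS_RE = re.compile(r"(?<![a-z])depress")


def matches_diagnosis_pattern(text: str) -> bool:
    """True iff the text contains words starting with both ``diagnos`` and ``depress``.

    This is the prefix search pattern used to harvest candidate diagnosis
    statements; it is deliberately broad ("diagnosing my depressing playlist"
    matches) — semantic screening of matches is a human step outside this
    package's scope.
    """
    low = text.lower()
    return bool(_DIAGNOSIS_RE.search(low)) and bool(_DEPRESS_RE.search(low))


_FIXED_OFFSET_RE = re.compile(
    r"^(?:UTC|GMT)?\s*([+\-−])\s*(\d{1,2})(?::?(\d{2}))?$"
)


def resolve_timezone(name: str) -> tzinfo:
    """Resolve an IANA zone name or fixed UTC offset string to a tzinfo.

    Accepts e.g. ``America/New_York``, ``UTC-05:00``, ``-05:00``, ``+0530``
    and the Unicode minus sign.  Raises :class:`LocalizationError` otherwise.
    """
    if not isinstance(name, str) or not name.strip():
        raise LocalizationError(f"unresolvable timezone: {name!r}")
    name = name.strip()
    if name.upper() in ("UTC", "GMT"):
        return timezone.utc
    match = _FIXED_OFFSET_RE.match(name)
    if match:
        sign = -1 if match.group(1) in "-−" else 1
        hours, minutes = int(match.group(2)), int(match.group(3) or 0)
        if hours > 23 or minutes > 59:
            raise LocalizationError(f"offset out of range: {name!r}")
        return timezone(sign * timedelta(hours=hours, minutes=minutes))
    try:
        return ZoneInfo(name)
    except Exception as exc:
        raise LocalizationError(f"unresolvable timezone: {name!r}") from exc


def _timezone_resolvable(name) -> bool:
    try:
        resolve_timezone(name)
        return True
    except LocalizationError:
        return False


def localize_hour(event: EventRecord, profile: UserProfile) -> int:
    """Local wall-clock hour (0..23) at which the event was posted.

    DST-aware for IANA zones: the UTC instant is converted with the offset
    rule in force at that instant.
    """
    zone = resolve_timezone(profile.timezone)
    return event.created_at_utc.astimezone(zone).hour


def localize_hours(events: pd.DataFrame, profiles: pd.DataFrame) -> pd.Series:
    """Vectorized local hour for every event, joined on ``user_id``.

    Events of users without a resolvable timezone raise; run
    :func:`filter_events` first.
    """
    tz_map = profiles.set_index("user_id")["timezone"]
    event_tz = events["user_id"].map(tz_map)
    if event_tz.isna().any():
        missing = events.loc[event_tz.isna(), "user_id"].iloc[0]
        raise LocalizationError(f"no profile/timezone for user {missing!r}")
    created = pd.to_datetime(events["created_at"], utc=True)
    hours = pd.Series(np.empty(len(events), dtype=np.int64), index=events.index)
    for zone_name in event_tz.unique():
        zone = resolve_timezone(zone_name)
        mask = (event_tz == zone_name).values
        hours[mask] = created[mask].dt.tz_convert(zone).dt.hour
    return hours


def _parse_event_row(row: dict) -> dict:
    for col in EVENT_COLUMNS:
        if col not in row or row[col] is None or (
            isinstance(row[col], float) and np.isnan(row[col])
        ):
            raise FormatError(f"missing field {col!r}")
    ts = row["created_at"]
    if isinstance(ts, str):
        ts = datetime.fromisoformat(ts.replace("Z", "+00:00"))
    if not isinstance(ts, datetime) or ts.tzinfo is None:
        raise FormatError("naive or unparseable timestamp")
    is_rt = row["is_retweet"]
    if isinstance(is_rt, str):
        is_rt = is_rt.strip().lower() in ("true", "1", "yes")
    return {
        "tweet_id": str(row["tweet_id"]),
        "user_id": str(row["user_id"]),
        "created_at": ts.astimezone(timezone.utc),
        "text": str(row["text"]),
        "is_retweet": bool(is_rt),
        "lang": str(row["lang"]),
    }


def _read_rows(path, fmt: Optional[str]) -> Iterable[dict]:
    path = str(path)
    if fmt is None:
        fmt = "csv" if path.endswith(".csv") else "jsonl"
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    yield json.loads(line)
                except json.JSONDecodeError:
                    yield {"__malformed__": line}
    elif fmt == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            yield from csv.DictReader(fh)
    else:
        raise FormatError(f"unknown format {fmt!r} (expected 'jsonl' or 'csv')")


def read_events(path, fmt: Optional[str] = None) -> Tuple[pd.DataFrame, int]:
    """Read and validate event records from JSONL or CSV.

    Returns the events table (in file order) and the count of malformed rows,
    which are skipped with a logged warning rather than silently dropped.
    A file whose header lacks a required column raises :class:`FormatError`.
    """
    rows: List[dict] = []
    malformed = 0
    first = True
    for raw in _read_rows(path, fmt):
        if first and "__malformed__" not in raw:
            missing = [c for c in EVENT_COLUMNS if c not in raw]
            if missing:
                raise FormatError(f"{path}: missing required column(s) {missing}")
            first = False
        try:
            if "__malformed__" in raw:
                raise FormatError("unparseable line")
            rows.append(_parse_event_row(raw))
        except (FormatError, ValueError) as exc:
            malformed += 1
            logger.warning("skipping malformed event row in %s: %s", path, exc)
    if rows:
        events = pd.DataFrame(rows)
        events["created_at"] = pd.to_datetime(events["created_at"], utc=True)
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS).astype({"created_at": "datetime64[ns, UTC]"}, errors="ignore")
    return events, malformed


def read_profiles(path, fmt: Optional[str] = None) -> Tuple[pd.DataFrame, int]:
    """Read user profile records; see :func:`read_events` for conventions."""
    rows: List[dict] = []
    malformed = 0
    first = True
    required = ["user_id", "timezone", "created_month"]
    for raw in _read_rows(path, fmt):
        if first and "__malformed__" not in raw:
            missing = [c for c in required if c not in raw]
            if missing:
                raise FormatError(f"{path}: missing required column(s) {missing}")
            first = False
        if "__malformed__" in raw or any(raw.get(c) in (None, "") for c in required):
            malformed += 1
            logger.warning("skipping malformed profile row in %s", path)
            continue
        rows.append(
            {
                "user_id": str(raw["user_id"]),
                "timezone": str(raw["timezone"]),
                "created_month": str(raw["created_month"]),
                "cohort": raw.get("cohort"),
            }
        )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS), malformed


def filter_events(
    events: pd.DataFrame,
    profiles: pd.DataFrame,
    malformed: int = 0,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Apply the study's event filters and account for every removal.

    Retained events are English-tagged, not retweets, do not match the
    diagnosis search pattern, and belong to a profiled user with a resolvable
    timezone.  Each removed event is counted under the first rule it violates,
    in the order retweet, non-English, diagnosis pattern, unknown user,
    no timezone.  Filtering is idempotent.
    """
    report = FilterReport(malformed=malformed)
    if events.empty:
        report.retained = 0
        return events.copy(), report

    resolvable = {
        row.user_id
        for row in profiles.itertuples()
        if _timezone_resolvable(row.timezone)
    }
    known = set(profiles["user_id"])

    is_rt = events["is_retweet"].astype(bool).values
    non_en = (events["lang"] != "en").values
    diag = events["text"].map(matches_diagnosis_pattern).values
    unknown = ~events["user_id"].isin(known).values
    no_tz = events["user_id"].isin(known - resolvable).values

    reason = np.full(len(events), "", dtype=object)
    for name, mask in [
        ("retweet", is_rt),
        ("non_english", non_en),
        ("diagnosis", diag),
        ("unknown_user", unknown),
        ("no_timezone", no_tz),
    ]:
        hit = mask & (reason == "")
        reason[hit] = name
        setattr(report, name, int(hit.sum()))

    keep = reason == ""
    report.retained = int(keep.sum())
    return events.loc[keep].reset_index(drop=True), report


def _largest_remainder_quotas(
    shares: Dict[str, float], target_n: int
) -> Dict[str, int]:
    """Apportion target_n across keys proportionally to shares (largest remainder)."""
    months = sorted(shares)
    ideal = np.array([shares[m] for m in months]) * target_n
    quotas = np.floor(ideal).astype(int)
    remainder = target_n - quotas.sum()
    if remainder > 0:
        frac = ideal - quotas
        # ties broken toward earlier months via stable sort on -frac
        order = np.argsort(-frac, kind="stable")
        quotas[order[:remainder]] += 1
    return dict(zip(months, quotas))


def matched_sample(
    candidates: pd.DataFrame,
    reference: pd.DataFrame,
    target_n: int,
    seed: int,
) -> List[str]:
    """Sample candidate users so their creation-month distribution matches a reference.

    Month quotas are the largest-remainder apportionment of ``target_n``
    across the reference's empirical creation-month distribution; within each
    month, users are drawn uniformly without replacement.  Candidates that
    appear in the reference are excluded first.  Months with reference mass
    but too few candidates raise :class:`MatchingError` naming every deficient
    month — quotas are never silently redistributed.
    """
    if target_n < 1:
        raise MatchingError(f"target_n must be >= 1, got {target_n}")
    ref_ids = set(reference["user_id"])
    pool = candidates[~candidates["user_id"].isin(ref_ids)]
    ref_counts = reference["created_month"].value_counts()
    shares = (ref_counts / ref_counts.sum()).to_dict()
    quotas = _largest_remainder_quotas(shares, target_n)

    by_month = {m: grp["user_id"].tolist() for m, grp in pool.groupby("created_month")}
    deficient = {
        m: (q, len(by_month.get(m, [])))
        for m, q in quotas.items()
        if q > len(by_month.get(m, []))
    }
    if deficient:
        detail = ", ".join(
            f"{m} (need {q}, have {avail})" for m, (q, avail) in sorted(deficient.items())
        )
        raise MatchingError(f"insufficient candidates for month(s): {detail}")

    rng = np.random.default_rng(seed)
    selected: List[str] = []
    for month in sorted(quotas):
        q = quotas[month]
        if q == 0:
            continue
        users = sorted(by_month[month])
        picked = rng.choice(len(users), size=q, replace=False)
        selected.extend(users[i] for i in picked)
    return selected
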