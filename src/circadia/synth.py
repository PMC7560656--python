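"""Synthetic two-cohort event-stream generator.

Generates tweet-like event records for a "depressed" (D) and a "random" (RS)
cohort whose hourly posting intensity follows a configurable 24-hour circadian
shape, with multiplicative hourly effects on the D cohort and token-category
emission at cohort-specific (optionally hour-specific) rates.  The generator
exists to exercise the analysis pipeline against a known ground truth; it makes
no attempt to imitate real language, social structure, or bursty posting beyond
the hourly rate model.

The default base shape encodes the circadian rhythm typical of online activity:
a night valley from roughly 10 PM to 6 AM, a first peak at noon, an afternoon
plateau, and the day's highest peak around 9 PM.  The default D-cohort effects
are +10% from 7 PM to midnight and -27% from 3 to 6 AM, applied as
multiplicative factors on the base intensity before renormalization; these are
stand-ins for empirically reported effect sizes, not a fitted model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateProfileError

__all__ = [
    "IntensityProfile",
    "TokenEmissionModel",
    "SyntheticConfig",
    "analytic_profile",
    "generate_dataset",
    "default_config",
    "default_token_model",
    "write_events_jsonl",
    "write_profiles_jsonl",
    "DEFAULT_BASE_RATE",
    "DEPRESSED_MULTIPLIERS",
    "EVENING_HOURS",
    "EARLY_MORNING_HOURS",
]

#: Hours of local day covered by the evening effect window (7 PM to midnight).
EVENING_HOURS: Tuple[int, ...] = (19, 20, 21, 22, 23)
#: Hours of local day covered by the early-morning effect window (3 to 6 AM).
EARLY_MORNING_HOURS: Tuple[int, ...] = (3, 4, 5)

#: Default base intensity (expected tweets per user per hour of local day, in
#: arbitrary units; only the normalized shape matters for hour placement).
#: Night valley ~10 PM-6 AM, noon peak, afternoon plateau, highest peak 9 PM.
DEFAULT_BASE_RATE = np.array(
    [
        3.0, 2.2, 1.6, 1.2, 1.0, 1.1,   # 0-5: night valley, minimum before dawn
        1.6, 2.8, 3.8, 4.6, 5.2, 5.6,   # 6-11: morning ramp
        6.0, 5.7, 5.6, 5.6, 5.7, 5.8,   # 12-17: noon peak then plateau
        5.9, 6.1, 6.4, 6.8, 5.0, 3.8,   # 18-23: evening rise, 9 PM peak, drop
    ]
)

#: Default multiplicative hourly effects for the D cohort: 1.10 on 19-23,
#: 0.73 on 3-5, 1.0 elsewhere.
DEPRESSED_MULTIPLIERS = np.ones(24)
DEPRESSED_MULTIPLIERS[list(EVENING_HOURS)] = 1.10
DEPRESSED_MULTIPLIERS[list(EARLY_MORNING_HOURS)] = 0.73


def _as_24_vector(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (24,):
        raise ConfigurationError(f"{name} must be a 24-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError(f"{name} must be finite")
    return arr


@dataclass
class IntensityProfile:
    """Hourly posting intensity for one cohort.

    Parameters
    ----------
    base_rate
        24-vector of nonnegative expected tweets per user per hour of local
        day (arbitrary units).
    effect_multipliers
        24-vector of positive multiplicative factors; 1.0 means no effect.
        The effective rate at hour ``h`` is ``base_rate[h] *
        effect_multipliers[h]``.
    """

    base_rate: np.ndarray = field(default_factory=lambda: DEFAULT_BASE_RATE.copy())
    effect_multipliers: np.ndarray = field(default_factory=lambda: np.ones(24))

    def __post_init__(self) -> None:
        self.base_rate = _as_24_vector(self.base_rate, "base_rate")
        self.effect_multipliers = _as_24_vector(
            self.effect_multipliers, "effect_multipliers"
        )
        if np.any(self.base_rate < 0):
            raise ConfigurationError("base_rate entries must be >= 0")
        if np.any(self.effect_multipliers <= 0):
            raise ConfigurationError("effect_multipliers entries must be > 0")

    @property
    def effective_rate(self) -> np.ndarray:
        return self.base_rate * self.effect_multipliers


def analytic_profile(profile: IntensityProfile) -> np.ndarray:
    """Expected hourly activity percentages implied by an intensity profile.

    Returns ``100 * rate[h] * mult[h] / sum_k rate[k] * mult[k]``; the result
    sums to 100 exactly.  This closed form is the ground-truth oracle against
    which empirical profiles of generated datasets converge.
    """
    eff = profile.effective_rate
    total = eff.sum()
    if total <= 0:
        raise DegenerateProfileError("all effective rates are zero")
    return 100.0 * eff / total


@dataclass
class TokenEmissionModel:
    """Per-tweet token emission rates for each category and cohort.

    ``rates[category][cohort]`` is the expected number of occurrences of that
    category's tokens per tweet.  ``hour_multipliers[category][cohort]`` is an
    optional 24-vector modulating the rate by local hour of posting (1.0 = no
    modulation).  Background filler tokens are emitted at ``background_rate``
    per tweet regardless of cohort.
    """

    vocabulary: Dict[str, List[str]]
    rates: Dict[str, Dict[str, float]]
    background_vocabulary: List[str] = field(default_factory=list)
    background_rate: float = 0.0
    hour_multipliers: Dict[str, Dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        background = set(self.background_vocabulary)
        for cat, tokens in self.vocabulary.items():
            if not tokens:
                raise ConfigurationError(f"category {cat!r} has an empty token list")
            clash = background.intersection(tokens)
            if clash:
                raise ConfigurationError(
                    f"category {cat!r} tokens overlap background vocabulary: {sorted(clash)}"
                )
            if cat not in self.rates:
                raise ConfigurationError(f"category {cat!r} has no emission rates")
        for cat, per_cohort in self.rates.items():
            if cat not in self.vocabulary:
                raise ConfigurationError(f"rates given for unknown category {cat!r}")
            for cohort, rate in per_cohort.items():
                if rate < 0:
                    raise ConfigurationError(
                        f"rates[{cat!r}][{cohort!r}] must be >= 0, got {rate}"
                    )
        if self.background_rate < 0:
            raise ConfigurationError("background_rate must be >= 0")
        for cat, per_cohort in self.hour_multipliers.items():
            for cohort, mults in per_cohort.items():
                arr = _as_24_vector(mults, f"hour_multipliers[{cat!r}][{cohort!r}]")
                if np.any(arr < 0):
                    raise ConfigurationError(
                        f"hour_multipliers[{cat!r}][{cohort!r}] must be >= 0"
                    )
                per_cohort[cohort] = arr

    def rate_by_hour(self, category: str, cohort: str) -> np.ndarray:
        """Effective emission rate of `category` in `cohort` for each local hour."""
        base = self.rates[category].get(cohort, 0.0)
        mults = self.hour_multipliers.get(category, {}).get(cohort)
        if mults is None:
            return np.full(24, base)
        return base * mults

    def lexicon(self) -> Dict[str, List[str]]:
        """Category -> token list mapping, for use as a content-analysis lexicon."""
        return {cat: list(tokens) for cat, tokens in self.vocabulary.items()}


_BACKGROUND_VOCAB = [
    "the", "a", "to", "and", "of", "in", "it", "is", "for", "on",
    "with", "at", "this", "but", "not", "are", "was", "so", "just", "like",
    "out", "up", "get", "go", "day", "time", "new", "one", "now", "all",
    "about", "from", "be", "have", "do", "see", "know", "work", "today", "night",
    "people", "really", "going", "got", "back", "when", "there", "here", "them", "then",
]


def default_token_model() -> TokenEmissionModel:
    """Six-category token model with D/RS rate ratios of realistic magnitude.

    The categories mirror the lexical dimensions used in content analyses of
    depression-related language (self-focus, affect, rumination, absolutist
    thinking); the D:RS rate ratios (1.8, 1.7, 1.45, 1.25, 1.25, 1.35) are in
    the range reported for such comparisons.
    """
    vocabulary = {
        "personal_pronouns": ["I", "me", "my", "myself", "mine"],
        "negative_affect": ["sad", "tired", "hurt", "cry", "alone"],
        "positive_affect": ["happy", "love", "great", "good", "\U0001F60A"],
        "rumination": ["thinking", "wish", "remember", "still", "again"],
        "questioning": ["why", "how", "what", "?"],
        "rigid_thinking": ["never", "always", "nothing", "everything"],
    }
    rates = {
        "personal_pronouns": {"RS": 0.25, "D": 0.45},   # ratio 1.80
        "negative_affect": {"RS": 0.10, "D": 0.17},     # ratio 1.70
        "positive_affect": {"RS": 0.20, "D": 0.29},     # ratio 1.45
        "rumination": {"RS": 0.12, "D": 0.15},          # ratio 1.25
        "questioning": {"RS": 0.12, "D": 0.15},         # ratio 1.25
        "rigid_thinking": {"RS": 0.10, "D": 0.135},     # ratio 1.35
    }
    return TokenEmissionModel(
        vocabulary=vocabulary,
        rates=rates,
        background_vocabulary=list(_BACKGROUND_VOCAB),
        background_rate=6.0,
    )


_DEFAULT_TIMEZONES = [
    "America/New_York",
    "America/Chicago",
    "America/Denver",
    "America/Los_Angeles",
    "Europe/London",
]


def _default_creation_months() -> Dict[str, float]:
    months = [f"{y}-{m:02d}" for y in (2015, 2016) for m in range(1, 13)]
    return {m: 1.0 / len(months) for m in months}


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic two-cohort dataset.

    ``tweets_per_user`` is a distribution spec: ``{"family": "lognormal",
    "mean_log": float, "sigma_log": float}`` (totals rounded and clipped to
    >= 1) or ``{"family": "constant", "value": int}``.  Per-user totals are
    heterogeneous and heavy-tailed by default, mimicking the skew of real
    posting activity.
    """

    n_users: Dict[str, int] = field(default_factory=lambda: {"D": 50, "RS": 200})
    tweets_per_user: Dict[str, float] = field(
        default_factory=lambda: {
            "family": "lognormal",
            "mean_log": float(np.log(100.0)),
            "sigma_log": 0.8,
        }
    )
    intensity: Dict[str, IntensityProfile] = field(
        default_factory=lambda: {
            "D": IntensityProfile(effect_multipliers=DEPRESSED_MULTIPLIERS.copy()),
            "RS": IntensityProfile(),
        }
    )
    token_model: Optional[TokenEmissionModel] = None
    creation_month_probs: Dict[str, float] = field(
        default_factory=_default_creation_months
    )
    timezones: List[str] = field(default_factory=lambda: list(_DEFAULT_TIMEZONES))
    date_start: date = date(2017, 1, 1)
    date_end: date = date(2018, 12, 31)
    seed: int = 0

    def __post_init__(self) -> None:
        for cohort, n in self.n_users.items():
            if n < 1:
                raise ConfigurationError(f"n_users[{cohort!r}] must be >= 1, got {n}")
            if cohort not in self.intensity:
                raise ConfigurationError(f"no intensity profile for cohort {cohort!r}")
        family = self.tweets_per_user.get("family")
        if family == "lognormal":
            sigma = self.tweets_per_user.get("sigma_log")
            if sigma is None or sigma < 0:
                raise ConfigurationError("tweets_per_user.sigma_log must be >= 0")
            if self.tweets_per_user.get("mean_log") is None:
                raise ConfigurationError("tweets_per_user.mean_log is required")
        elif family == "constant":
            value = self.tweets_per_user.get("value")
            if value is None or value < 1:
                raise ConfigurationError("tweets_per_user.value must be >= 1")
        else:
            raise ConfigurationError(
                f"tweets_per_user.family must be 'lognormal' or 'constant', got {family!r}"
            )
        total_p = sum(self.creation_month_probs.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ConfigurationError(
                f"creation_month_probs must sum to 1 (got {total_p!r})"
            )
        if not self.timezones:
            raise ConfigurationError("timezones pool must be nonempty")
        if self.date_end < self.date_start:
            raise ConfigurationError("date_end must be on or after date_start")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SyntheticConfig":
        """Build a config from a plain JSON-style mapping."""
        kwargs = dict(raw)
        if "intensity" in kwargs:
            kwargs["intensity"] = {
                cohort: IntensityProfile(**spec) if isinstance(spec, Mapping) else spec
                for cohort, spec in kwargs["intensity"].items()
            }
        if isinstance(kwargs.get("token_model"), Mapping):
            kwargs["token_model"] = TokenEmissionModel(**kwargs["token_model"])
        for key in ("date_start", "date_end"):
            if isinstance(kwargs.get(key), str):
                kwargs[key] = date.fromisoformat(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def default_config(**overrides) -> SyntheticConfig:
    """The default study conditions with an attached default token model."""
    cfg = SyntheticConfig(**overrides)
    if cfg.token_model is None and "token_model" not in overrides:
        cfg.token_model = default_token_model()
    return cfg


def _draw_totals(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    spec = cfg.tweets_per_user
    if spec["family"] == "constant":
        return np.full(n, int(spec["value"]), dtype=np.int64)
    raw = rng.lognormal(mean=spec["mean_log"], sigma=spec["sigma_log"], size=n)
    return np.maximum(np.rint(raw).astype(np.int64), 1)


def _emit_texts(
    model: TokenEmissionModel,
    cohort: str,
    hours: np.ndarray,
    rng: np.random.Generator,
) -> List[str]:
    """Draw each tweet's text as a space-joined token sample.

    Category token counts are Poisson at the cohort's (hour-modulated) rate;
    tokens within a category are chosen uniformly.  Background filler tokens
    are appended at the background rate.
    """
    n = hours.shape[0]
    idx_parts: List[np.ndarray] = []
    tok_parts: List[np.ndarray] = []
    for cat in sorted(model.vocabulary):
        per_hour = model.rate_by_hour(cat, cohort)
        lam = per_hour[hours]
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        idx_parts.append(np.repeat(np.arange(n), counts))
        tok_parts.append(rng.choice(np.asarray(model.vocabulary[cat], dtype=object), size=total))
    if model.background_rate > 0 and model.background_vocabulary:
        counts = rng.poisson(model.background_rate, size=n)
        total = int(counts.sum())
        if total > 0:
            idx_parts.append(np.repeat(np.arange(n), counts))
            tok_parts.append(
                rng.choice(np.asarray(model.background_vocabulary, dtype=object), size=total)
            )
    if not idx_parts:
        return [""] * n
    idx = np.concatenate(idx_parts)
    toks = np.concatenate(tok_parts)
    order = np.argsort(idx, kind="stable")
    idx, toks = idx[order], toks[order]
    bounds = np.searchsorted(idx, np.arange(n + 1))
    return [" ".join(toks[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]


def generate_dataset(cfg: SyntheticConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate event and profile tables for all configured cohorts.

    Returns
    -------
    events, profiles
        ``events`` has columns ``tweet_id, user_id, created_at (UTC),
        text, is_retweet, lang``; ``profiles`` has ``user_id, timezone,
        created_month, cohort``.  Each event's local wall-clock hour is drawn
        categorically from the cohort's normalized effective intensity;
        minute/second and calendar date are uniform.  Identical
        (config, seed) pairs yield identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    months = sorted(cfg.creation_month_probs)
    month_p = np.array([cfg.creation_month_probs[m] for m in months])
    n_days = (cfg.date_end - cfg.date_start).days + 1
    start_ts = pd.Timestamp(cfg.date_start)

    event_frames, profile_frames = [], []
    for cohort in sorted(cfg.n_users):
        n = cfg.n_users[cohort]
        user_ids = np.array([f"{cohort}_{i:06d}" for i in range(n)], dtype=object)
        tz = rng.choice(np.asarray(cfg.timezones, dtype=object), size=n)
        created = rng.choice(np.asarray(months, dtype=object), size=n, p=month_p)
        totals = _draw_totals(cfg, n, rng)
        profile_frames.append(
            pd.DataFrame(
                {
                    "user_id": user_ids,
                    "timezone": tz,
                    "created_month": created,
                    "cohort": cohort,
                }
            )
        )

        p = analytic_profile(cfg.intensity[cohort]) / 100.0
        m = int(totals.sum())
        hours = rng.choice(24, size=m, p=p)
        days = rng.integers(0, n_days, size=m)
        minutes = rng.integers(0, 60, size=m)
        seconds = rng.integers(0, 60, size=m)
        user_idx = np.repeat(np.arange(n), totals)

        local_naive = (
            start_ts
            + pd.to_timedelta(days, unit="D")
            + pd.to_timedelta(hours, unit="h")
            + pd.to_timedelta(minutes, unit="m")
            + pd.to_timedelta(seconds, unit="s")
        )
        # Localize per timezone group; spring-forward gaps are shifted ahead
        # (affects < 0.02% of events), fall-back folds resolve to the DST side.
        created_utc = pd.Series(pd.NaT, index=np.arange(m), dtype="datetime64[ns, UTC]")
        event_tz = tz[user_idx]
        local_series = pd.Series(local_naive)
        for zone in np.unique(event_tz):
            mask = event_tz == zone
            created_utc[mask] = (
                local_series[mask]
                .dt.tz_localize(zone, ambiguous=True, nonexistent="shift_forward")
                .dt.tz_convert("UTC")
            )

        if cfg.token_model is not None:
            texts = _emit_texts(cfg.token_model, cohort, hours, rng)
        else:
            texts = [""] * m
        event_frames.append(
            pd.DataFrame(
                {
                    "tweet_id": [f"{cohort}_t{i:08d}" for i in range(m)],
                    "user_id": user_ids[user_idx],
                    "created_at": created_utc.array,
                    "text": texts,
                    "is_retweet": False,
                    "lang": "en",
                }
            )
        )

    events = pd.concat(event_frames, ignore_index=True)
    profiles = pd.concat(profile_frames, ignore_index=True)
    return events, profiles


def write_events_jsonl(events: pd.DataFrame, path) -> None:
    """Write events as JSONL with ISO-8601 UTC timestamps."""
    out = events.copy()
    out["created_at"] = (
        pd.to_datetime(out["created_at"], utc=True)
        .dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
    )
    with open(path, "w", encoding="utf-8") as fh:
        for rec in out.to_dict(orient="records"):
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def write_profiles_jsonl(profiles: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in profiles.to_dict(orient="records"):
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
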