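"""Tweet content analysis: tokenization, hour-consistent token selection, and
category prevalence ratios.

The *prevalence* f(t) of a token in a cohort is the expected number of its
occurrences per tweet; a category's prevalence pools its tokens' prevalences,
and the *prevalence ratio* PR = f_D / f_RS compares the depressed cohort to
the random cohort (PR > 1: relative overuse by the depressed cohort).  Hourly
prevalence-ratio series are z-score normalized to expose the within-day shape
independent of a category's overall level.

To keep hourly comparisons meaningful, analyses restrict to tokens that are
frequent at every hour of the day in both cohorts: the intersection of the
per-hour top-k token lists (k = 250 by default) across all 24 hours of both
cohorts.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateCohortError, SparseHourError, UndefinedRatioError

__all__ = [
    "TokenCategory",
    "PrevalenceResult",
    "tokenize",
    "load_lexicon",
    "top_tokens_per_hour",
    "consistent_tokens",
    "token_prevalence",
    "category_prevalence_ratio",
    "hourly_prevalence_series",
]

logger = logging.getLogger(__name__)

# Social-media-aware token pattern: URLs, @mentions, #hashtags, words with
# internal apostrophes, numbers, emoji, and punctuation runs each stay one
# token.
_EMOJI = (
    "\U0001F000-\U0001FAFF"  # emoji & pictographs, incl. flags
    "☀-➿"          # misc symbols and dingbats
    "⬀-⯿"
    "️"
)
_TOKEN_RE = re.compile(
    rf"""
    https?://\S+ | www\.\S+          # URLs
    | @\w+                           # mentions
    | \#\w+                          # hashtags
    | [A-Za-z][A-Za-z0-9]*(?:['’][A-Za-z]+)*   # words, contractions kept whole
    | \d+(?:[.,]\d+)*                # numbers
    | [{_EMOJI}]                     # emoji
    | [!?.]+                         # terminal punctuation runs
    | [^\w\s]                        # any other symbol, alone
    """,
    re.VERBOSE,
)

# Unambiguous contractions only; forms like "he's" (is/has) pass through.
_CONTRACTIONS: Dict[str, List[str]] = {
    "i'm": ["I", "am"],
    "i'll": ["I", "will"],
    "i've": ["I", "have"],
    "i'd": ["I", "would"],
    "you'll": ["you", "will"],
    "you've": ["you", "have"],
    "we're": ["we", "are"],
    "they're": ["they", "are"],
    "can't": ["can", "not"],
    "won't": ["will", "not"],
    "don't": ["do", "not"],
    "didn't": ["did", "not"],
    "isn't": ["is", "not"],
    "aren't": ["are", "not"],
    "wasn't": ["was", "not"],
    "weren't": ["were", "not"],
    "couldn't": ["could", "not"],
    "shouldn't": ["should", "not"],
    "wouldn't": ["would", "not"],
}


def _decapitalize(token: str) -> str:
    # Lowercase only tokens whose sole capital is the initial letter; "I" and
    # multi-capital tokens (acronyms, camel case) keep their form.
    if token == "I":
        return token
    caps = sum(1 for ch in token if ch.isupper())
    if caps == 1 and token[0].isupper():
        return token.lower()
    return token


def tokenize(text: str) -> List[str]:
    """Tokenize a tweet, normalize capitalization, expand unambiguous contractions.

    Emoji, hashtags and mentions each survive as single tokens.  A token whose
    only capital letter is its first character is lowercased, except "I".
    Unambiguous contractions are replaced by their expansions ("I'm" → "I",
    "am"); ambiguous ones ("he's") pass through unchanged.  Idempotent on its
    own output.
    """
    out: List[str] = []
    for raw in _TOKEN_RE.findall(text):
        token = _decapitalize(raw)
        expansion = _CONTRACTIONS.get(token.replace("’", "'").lower())
        if expansion is not None:
            out.extend(expansion)
        else:
            out.append(token)
    return out


@dataclass(frozen=True)
class TokenCategory:
    """A named token category (e.g. rumination) as a set of token strings."""

    name: str
    tokens: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ConfigurationError(f"category {self.name!r} has no tokens")
        object.__setattr__(self, "tokens", frozenset(self.tokens))


def load_lexicon(
    source: Union[str, Mapping[str, Sequence[str]]],
    allow_overlap: bool = False,
) -> List[TokenCategory]:
    """Load category lexicons from a JSON file path or an in-memory mapping.

    By default token sets must be disjoint across categories; pass
    ``allow_overlap=True`` when a configuration deliberately shares tokens.
    """
    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        with open(source, encoding="utf-8") as fh:
            mapping = json.load(fh)
    else:
        mapping = source
    categories = [TokenCategory(name, frozenset(toks)) for name, toks in mapping.items()]
    if not allow_overlap:
        seen: Dict[str, str] = {}
        for cat in categories:
            for tok in cat.tokens:
                if tok in seen:
                    raise ConfigurationError(
                        f"token {tok!r} appears in both {seen[tok]!r} and {cat.name!r}"
                    )
                seen[tok] = cat.name
    return categories


TweetsLike = Union[Sequence[str], Sequence[Sequence[str]]]


def _as_token_lists(tweets: TweetsLike) -> List[List[str]]:
    out: List[List[str]] = []
    for tweet in tweets:
        out.append(tokenize(tweet) if isinstance(tweet, str) else list(tweet))
    return out


def top_tokens_per_hour(
    tweets: pd.DataFrame, k: int, text_col: str = "text", hour_col: str = "hour"
) -> Dict[int, List[str]]:
    """The k most used tokens for each local hour of the day.

    ``tweets`` needs a text column and a local-hour column.  Tokens are ranked
    per hour by total occurrence count; count ties break lexicographically.
    An hour with no tweets yields an empty list and a logged warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    result: Dict[int, List[str]] = {}
    grouped = dict(tuple(tweets.groupby(hour_col)))
    for hour in range(24):
        grp = grouped.get(hour)
        if grp is None or grp.empty:
            logger.warning("no tweets at hour %d; top-token list is empty", hour)
            result[hour] = []
            continue
        counts: Counter = Counter()
        for text in grp[text_col]:
            counts.update(tokenize(text) if isinstance(text, str) else text)
        ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
        result[hour] = [tok for tok, _ in ranked[:k]]
    return result


def consistent_tokens(
    hourly_d: Mapping[int, Sequence[str]],
    hourly_rs: Mapping[int, Sequence[str]],
) -> Set[str]:
    """Tokens present in the top-k list of every hour of every cohort.

    The intersection runs over all 48 hourly lists (24 hours × 2 cohorts);
    any empty hourly list makes consistency undefined and raises.
    """
    lists = [hourly_d[h] for h in range(24)] + [hourly_rs[h] for h in range(24)]
    for i, lst in enumerate(lists):
        if not lst:
            raise SparseHourError(
                f"hour {i % 24} of cohort {'D' if i < 24 else 'RS'} has an empty top-token list"
            )
    common = set(lists[0])
    for lst in lists[1:]:
        common &= set(lst)
    return common


def token_prevalence(tweets: TweetsLike, token: str) -> float:
    """Expected occurrences of ``token`` per tweet (counted per instance)."""
    token_lists = _as_token_lists(tweets)
    if not token_lists:
        raise DegenerateCohortError("cannot compute prevalence of an empty tweet list")
    occurrences = sum(toks.count(token) for toks in token_lists)
    return occurrences / len(token_lists)


def _category_prevalence(token_lists: List[List[str]], tokens: FrozenSet[str]) -> float:
    counts: Counter = Counter()
    for toks in token_lists:
        counts.update(toks)
    return sum(counts[t] for t in tokens) / len(token_lists)


@dataclass
class PrevalenceResult:
    """Overall and hourly prevalence comparison of one category between cohorts."""

    category: str
    f_d: float
    f_rs: float
    pr: float
    token_ratios: Dict[str, Optional[float]] = field(default_factory=dict)
    hourly_pr: Optional[np.ndarray] = None
    hourly_mean: Optional[float] = None
    z_hourly: Optional[np.ndarray] = None


def category_prevalence_ratio(
    category: TokenCategory, tweets_d: TweetsLike, tweets_rs: TweetsLike
) -> PrevalenceResult:
    """Prevalence ratio of a category between the D and RS cohorts.

    Prevalences are pooled over the category's tokens before dividing (robust
    to rare tokens); per-token ratios are also reported, with None where a
    token never occurs in the RS cohort.
    """
    lists_d = _as_token_lists(tweets_d)
    lists_rs = _as_token_lists(tweets_rs)
    if not lists_d or not lists_rs:
        raise DegenerateCohortError("both tweet sets must be nonempty")
    f_d = _category_prevalence(lists_d, category.tokens)
    f_rs = _category_prevalence(lists_rs, category.tokens)
    if f_rs == 0:
        raise UndefinedRatioError(
            f"category {category.name!r} has zero prevalence in the RS cohort"
        )
    token_ratios: Dict[str, Optional[float]] = {}
    for tok in sorted(category.tokens):
        ft_d = token_prevalence(lists_d, tok)
        ft_rs = token_prevalence(lists_rs, tok)
        token_ratios[tok] = (ft_d / ft_rs) if ft_rs > 0 else None
    return PrevalenceResult(
        category=category.name,
        f_d=f_d,
        f_rs=f_rs,
        pr=f_d / f_rs,
        token_ratios=token_ratios,
    )


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()  # population sd
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def hourly_prevalence_series(
    category: TokenCategory,
    tweets_d: pd.DataFrame,
    tweets_rs: pd.DataFrame,
    text_col: str = "text",
    hour_col: str = "hour",
) -> PrevalenceResult:
    """Hourly prevalence-ratio series of a category, with mean and z-scores.

    ``hourly_pr[h]`` is the category prevalence ratio restricted to tweets
    posted at local hour h; every hour must hold at least one tweet in both
    cohorts (an empty stratum raises :class:`SparseHourError` naming the
    hour — merge hours or enlarge the data instead of propagating NaN).
    z-scores use the population standard deviation and are all zero for a
    constant series.
    """
    overall = category_prevalence_ratio(
        category, list(tweets_d[text_col]), list(tweets_rs[text_col])
    )
    by_hour_d = dict(tuple(tweets_d.groupby(hour_col)))
    by_hour_rs = dict(tuple(tweets_rs.groupby(hour_col)))
    hourly = np.empty(24)
    for hour in range(24):
        grp_d, grp_rs = by_hour_d.get(hour), by_hour_rs.get(hour)
        if grp_d is None or grp_d.empty:
            raise SparseHourError(f"no D-cohort tweets at hour {hour}")
        if grp_rs is None or grp_rs.empty:
            raise SparseHourError(f"no RS-cohort tweets at hour {hour}")
        lists_d = _as_token_lists(list(grp_d[text_col]))
        lists_rs = _as_token_lists(list(grp_rs[text_col]))
        f_d = _category_prevalence(lists_d, category.tokens)
        f_rs = _category_prevalence(lists_rs, category.tokens)
        if f_rs == 0:
            raise UndefinedRatioError(
                f"category {category.name!r} unused in RS cohort at hour {hour}"
            )
        hourly[hour] = f_d / f_rs
    overall.hourly_pr = hourly
    overall.hourly_mean = float(hourly.mean())
    overall.z_hourly = _zscore(hourly)
    return overall
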