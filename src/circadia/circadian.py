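"""Circadian activity profiles, user-level bootstraps, and phase-shift testing.

An *activity profile* is the 24-vector of percentages of a user's (or
cohort's) posts falling in each local hour of day; under uniform posting every
hour holds 100/24 ≈ 4.17%.  Cohort profiles use pooled normalization: all
users' hourly counts are summed before dividing by the grand total, so
prolific posters contribute proportionally more and the influence of users
with few posts is minimized.

Sampling variability at the cohort level is quantified by bootstrapping
*users* (not posts): each replicate redraws n users with replacement and
recomputes the pooled profile.  Between-cohort differences are bootstrapped by
resampling both cohorts independently within each replicate; an hour is
flagged significant when the 95% percentile interval of the difference
excludes zero.  A phase shift between two profiles is tested by wrapped
cross-correlation over integer lags −12..+12 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateCohortError,
    DegenerateProfileError,
    UndefinedCorrelationError,
    UndefinedRatioError,
)
from .ingest import localize_hours

__all__ = [
    "HourlyCounts",
    "BootstrapSummary",
    "DifferenceSummary",
    "PhaseShiftResult",
    "user_hourly_counts",
    "cohort_hourly_counts",
    "user_activity_profile",
    "cohort_activity_profile",
    "bootstrap_profile",
    "bootstrap_difference",
    "relative_difference",
    "cross_correlation_phase",
]

_BOOTSTRAP_CHUNK = 2000  # replicates per multinomial/matmul block


@dataclass(frozen=True)
class HourlyCounts:
    """Tweets posted by one user in each local hour of day."""

    user_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (24,) or np.any(counts < 0):
            raise ValueError("counts must be a nonnegative 24-vector")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BootstrapSummary:
    """Per-hour median and 95% percentile CI of bootstrapped activity levels."""

    median: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    n_replicates: int
    seed: int
    n_redrawn: int = 0


@dataclass(frozen=True)
class DifferenceSummary:
    """Bootstrapped per-hour D − RS profile difference (percentage points).

    ``significant[h]`` is True exactly when the CI at hour h excludes zero.
    """

    median: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    significant: np.ndarray
    n_replicates: int
    seed: int
    n_redrawn: int = 0


@dataclass(frozen=True)
class PhaseShiftResult:
    """Wrapped cross-correlation over lags −12..+12 h between two profiles."""

    lags: np.ndarray
    correlation: np.ndarray
    best_lag: int
    best_r: float


CountsLike = Union[Sequence[HourlyCounts], np.ndarray]


def _as_matrix(hcs: CountsLike) -> np.ndarray:
    if isinstance(hcs, np.ndarray):
        mat = np.asarray(hcs, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 24:
            raise ValueError("counts matrix must have shape (n_users, 24)")
        return mat
    return np.array([hc.counts for hc in hcs], dtype=float)


def user_hourly_counts(events: pd.DataFrame, profile) -> HourlyCounts:
    """Bin one user's (filtered) events by local hour of posting."""
    from .ingest import UserProfile  # local to avoid a circular hint in docs

    if isinstance(profile, UserProfile):
        profiles = pd.DataFrame(
            [
                {
                    "user_id": profile.user_id,
                    "timezone": profile.timezone,
                    "created_month": profile.created_month,
                    "cohort": profile.cohort,
                }
            ]
        )
        user_id = profile.user_id
    else:
        profiles = profile
        user_id = profiles["user_id"].iloc[0]
    counts = np.zeros(24, dtype=np.int64)
    if len(events):
        hours = localize_hours(events, profiles)
        counts = np.bincount(hours, minlength=24).astype(np.int64)
    return HourlyCounts(user_id=user_id, counts=counts)


def cohort_hourly_counts(
    events: pd.DataFrame, profiles: pd.DataFrame
) -> Tuple[List[str], np.ndarray]:
    """Per-user hourly count matrix for a whole cohort.

    Returns the sorted user ids (users with zero retained events excluded —
    they cannot contribute a profile) and the aligned (n_users, 24) matrix.
    """
    if events.empty:
        raise DegenerateCohortError("cohort has no events")
    hours = localize_hours(events, profiles)
    table = (
        pd.crosstab(events["user_id"], hours)
        .reindex(columns=range(24), fill_value=0)
        .sort_index()
    )
    users = [str(u) for u in table.index]
    return users, table.to_numpy(dtype=np.int64)


def user_activity_profile(hc: HourlyCounts) -> np.ndarray:
    """Hourly percentages of one user's daily activity (sums to 100)."""
    if hc.total == 0:
        raise DegenerateProfileError(f"user {hc.user_id} has no tweets")
    return 100.0 * hc.counts / hc.total


def cohort_activity_profile(hcs: CountsLike) -> np.ndarray:
    """Pooled cohort activity profile: summed counts over the grand total."""
    mat = _as_matrix(hcs)
    if mat.shape[0] == 0:
        raise DegenerateCohortError("empty cohort")
    pooled = mat.sum(axis=0)
    total = pooled.sum()
    if total <= 0:
        raise DegenerateCohortError("cohort has zero total tweets")
    return 100.0 * pooled / total


def _resample_block(
    counts: np.ndarray, m: int, rng: np.random.Generator
) -> Tuple[np.ndarray, int]:
    """m bootstrap profiles of one cohort.

    Resampling n users with replacement is realized as multinomial resample
    weights over users followed by a weighted pooling — per replicate this is
    exactly the pooled profile of the resampled multiset.  Replicates whose
    resample holds zero tweets in total are redrawn (keeping the replicate
    count fixed); their occurrences are counted.
    """
    n = counts.shape[0]
    weights = rng.multinomial(n, np.full(n, 1.0 / n), size=m).astype(float)
    pooled = weights @ counts
    totals = pooled.sum(axis=1)
    redrawn = 0
    while np.any(totals == 0):
        bad = np.flatnonzero(totals == 0)
        redrawn += bad.size
        weights = rng.multinomial(n, np.full(n, 1.0 / n), size=bad.size).astype(float)
        pooled[bad] = weights @ counts
        totals[bad] = pooled[bad].sum(axis=1)
    return 100.0 * pooled / totals[:, None], redrawn


def _percentiles(alpha: float) -> Tuple[float, float]:
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return 100 * alpha / 2, 100 * (1 - alpha / 2)


def bootstrap_profile(
    hcs: CountsLike,
    n_replicates: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapSummary:
    """Bootstrap a cohort's activity profile by resampling users with replacement.

    Each of the ``n_replicates`` replicates redraws n = cohort-size users with
    replacement and recomputes the pooled profile; the per-hour distribution is
    summarized by its median and percentile (alpha/2, 1−alpha/2) bounds.
    Deterministic for a given seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    counts = _as_matrix(hcs)
    if counts.shape[0] == 0:
        raise DegenerateCohortError("empty cohort")
    rng = np.random.default_rng(seed)
    lo_q, hi_q = _percentiles(alpha)
    profiles = np.empty((n_replicates, 24))
    redrawn = 0
    done = 0
    while done < n_replicates:
        m = min(_BOOTSTRAP_CHUNK, n_replicates - done)
        block, r = _resample_block(counts, m, rng)
        profiles[done : done + m] = block
        redrawn += r
        done += m
    return BootstrapSummary(
        median=np.median(profiles, axis=0),
        lower95=np.percentile(profiles, lo_q, axis=0),
        upper95=np.percentile(profiles, hi_q, axis=0),
        n_replicates=n_replicates,
        seed=seed,
        n_redrawn=redrawn,
    )


def bootstrap_difference(
    hcs_d: CountsLike,
    hcs_rs: CountsLike,
    n_replicates: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> DifferenceSummary:
    """Bootstrap the per-hour D − RS profile difference.

    Within each replicate both cohorts are resampled independently, the pooled
    profiles recomputed, and their difference (percentage points) recorded.
    An hour is flagged significant when the resulting percentile CI excludes
    zero (two-sided test at level alpha).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    counts_d = _as_matrix(hcs_d)
    counts_rs = _as_matrix(hcs_rs)
    if counts_d.shape[0] == 0 or counts_rs.shape[0] == 0:
        raise DegenerateCohortError("both cohorts must be nonempty")
    rng = np.random.default_rng(seed)
    lo_q, hi_q = _percentiles(alpha)
    diffs = np.empty((n_replicates, 24))
    redrawn = 0
    done = 0
    while done < n_replicates:
        m = min(_BOOTSTRAP_CHUNK, n_replicates - done)
        block_d, r_d = _resample_block(counts_d, m, rng)
        block_rs, r_rs = _resample_block(counts_rs, m, rng)
        diffs[done : done + m] = block_d - block_rs
        redrawn += r_d + r_rs
        done += m
    lower = np.percentile(diffs, lo_q, axis=0)
    upper = np.percentile(diffs, hi_q, axis=0)
    return DifferenceSummary(
        median=np.median(diffs, axis=0),
        lower95=lower,
        upper95=upper,
        significant=(lower > 0) | (upper < 0),
        n_replicates=n_replicates,
        seed=seed,
        n_redrawn=redrawn,
    )


def relative_difference(a_d: np.ndarray, a_rs: np.ndarray) -> np.ndarray:
    """Hourly activity ratio D/RS; 1.0 at an hour means equal activity levels."""
    a_d = np.asarray(a_d, dtype=float)
    a_rs = np.asarray(a_rs, dtype=float)
    zero = np.flatnonzero(a_rs == 0)
    if zero.size:
        raise UndefinedRatioError(
            f"reference profile is zero at hour(s) {zero.tolist()}"
        )
    return a_d / a_rs


def cross_correlation_phase(a_d: np.ndarray, a_rs: np.ndarray) -> PhaseShiftResult:
    """Wrapped cross-correlation phase test between two 24-point profiles.

    For every integer lag L in −12..+12 the Pearson correlation between
    ``a_d`` and ``a_rs`` circularly shifted by −L is computed on the full
    24-point overlap (the window wraps, never truncates).  ``best_lag`` is the
    lag of maximum correlation; exact ties resolve to the smallest |L|, then
    to the negative lag.  A circadian rhythm common to both cohorts with no
    phase shift shows its maximum at lag 0.
    """
    a_d = np.asarray(a_d, dtype=float)
    a_rs = np.asarray(a_rs, dtype=float)
    if a_d.shape != (24,) or a_rs.shape != (24,):
        raise ValueError("profiles must be 24-vectors")
    if np.ptp(a_d) == 0 or np.ptp(a_rs) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant profile")
    lags = np.arange(-12, 13)
    corr = np.array(
        [np.corrcoef(a_d, np.roll(a_rs, -int(lag)))[0, 1] for lag in lags]
    )
    best = corr.max()
    candidates = [int(lag) for lag, r in zip(lags, corr) if r >= best - 1e-12]
    best_lag = min(candidates, key=lambda lag: (abs(lag), lag))
    best_r = float(corr[list(lags).index(best_lag)])
    return PhaseShiftResult(lags=lags, correlation=corr, best_lag=best_lag, best_r=best_r)
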