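"""Activity profiles, user-level bootstraps, and phase detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circadia import (
    HourlyCounts,
    UserProfile,
    bootstrap_difference,
    bootstrap_profile,
    cohort_activity_profile,
    cross_correlation_phase,
    relative_difference,
    user_activity_profile,
    user_hourly_counts,
)
from circadia.exceptions import (
    DegenerateCohortError,
    DegenerateProfileError,
    UndefinedCorrelationError,
    UndefinedRatioError,
)
from conftest import make_events, make_profiles


def hc(counts, user="u"):
    return HourlyCounts(user, np.asarray(counts))


def at_hours(**hour_counts):
    counts = np.zeros(24, dtype=int)
    for key, value in hour_counts.items():
        counts[int(key[1:])] = value
    return counts


class TestHourlyCounts:
    def test_one_event_per_hour(self):
        events = make_events(range(24))
        profile = UserProfile("u1", "UTC", "2015-01")
        assert user_hourly_counts(events, profile).counts.tolist() == [1] * 24

    def test_all_events_in_one_hour(self):
        events = make_events([21] * 10)
        counts = user_hourly_counts(events, UserProfile("u1", "UTC", "2015-01")).counts
        assert counts[21] == 10 and counts.sum() == 10

    def test_empty_event_list_gives_zero_counts(self):
        events = make_events([])
        counts = user_hourly_counts(events, UserProfile("u1", "UTC", "2015-01")).counts
        assert counts.sum() == 0

    def test_counts_follow_local_not_utc_hour(self):
        events = make_events([3])  # 03:30 UTC in June is 23:30 in New York
        profile = UserProfile("u1", "America/New_York", "2015-01")
        assert user_hourly_counts(events, profile).counts[23] == 1


class TestActivityProfiles:
    def test_uniform_user_hits_the_uniform_reference(self):
        prof = user_activity_profile(hc([1] * 24))
        assert prof == pytest.approx(np.full(24, 100 / 24))

    def test_single_hour_user(self):
        prof = user_activity_profile(hc(at_hours(h21=10)))
        assert prof[21] == 100.0

    def test_simple_arithmetic(self):
        prof = user_activity_profile(hc(at_hours(h0=3, h1=1)))
        assert prof[0] == 75.0 and prof[1] == 25.0

    def test_zero_total_user_is_degenerate(self):
        with pytest.raises(DegenerateProfileError):
            user_activity_profile(hc([0] * 24))

    def test_pooled_normalization_weighs_heavy_posters(self):
        # u1: 3 tweets at hour 0, u2: 1 tweet at hour 12 -> 75% / 25%
        prof = cohort_activity_profile([hc(at_hours(h0=3)), hc(at_hours(h12=1))])
        assert prof[0] == 75.0 and prof[12] == 25.0

    def test_single_user_cohort_equals_user_profile(self):
        counts = at_hours(h1=2, h5=3, h20=5)
        assert cohort_activity_profile([hc(counts)]) == pytest.approx(
            user_activity_profile(hc(counts))
        )

    def test_identical_users_preserve_the_profile(self):
        counts = at_hours(h1=2, h5=3)
        one = cohort_activity_profile([hc(counts)])
        two = cohort_activity_profile([hc(counts), hc(counts)])
        assert two == pytest.approx(one)

    def test_empty_cohort_is_degenerate(self):
        with pytest.raises(DegenerateCohortError):
            cohort_activity_profile([])

    @given(
        mat=st.lists(
            st.lists(st.integers(0, 20), min_size=24, max_size=24),
            min_size=1,
            max_size=8,
        ).filter(lambda rows: any(any(r) for r in rows))
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_all_profiles_sum_to_100(self, mat):
        prof = cohort_activity_profile(np.array(mat, dtype=float))
        assert prof.sum() == pytest.approx(100.0, abs=1e-9)


class TestBootstrapProfile:
    def test_single_user_cohort_has_zero_ci_width(self):
        summary = bootstrap_profile([hc(at_hours(h3=4, h9=6))], n_replicates=200, seed=0)
        assert summary.lower95 == pytest.approx(summary.upper95)
        assert summary.median == pytest.approx(
            user_activity_profile(hc(at_hours(h3=4, h9=6)))
        )

    def test_homogeneous_cohort_median_tracks_point_estimate(self, rng):
        counts = rng.poisson(5.0, size=(200, 24))
        summary = bootstrap_profile(counts.astype(float), n_replicates=2000, seed=1)
        point = cohort_activity_profile(counts.astype(float))
        assert np.abs(summary.median - point).max() < 0.15
        assert np.all(summary.lower95 <= summary.median + 1e-12)
        assert np.all(summary.median <= summary.upper95 + 1e-12)

    def test_deterministic_given_seed(self, rng):
        counts = rng.poisson(3.0, size=(30, 24)).astype(float)
        a = bootstrap_profile(counts, n_replicates=500, seed=7)
        b = bootstrap_profile(counts, n_replicates=500, seed=7)
        assert np.array_equal(a.lower95, b.lower95)
        assert np.array_equal(a.upper95, b.upper95)

    def test_default_replicates_is_ten_thousand(self):
        import inspect

        assert inspect.signature(bootstrap_profile).parameters["n_replicates"].default == 10_000

    def test_zero_total_users_possible_replicates_are_redrawn(self):
        # one user with tweets, one without: a resample can hold only the
        # empty user; those replicates are redrawn, keeping the count fixed
        counts = np.array([at_hours(h5=3), np.zeros(24, dtype=int)], dtype=float)
        summary = bootstrap_profile(counts, n_replicates=500, seed=2)
        assert summary.n_replicates == 500
        assert summary.n_redrawn > 0
        assert summary.median == pytest.approx(np.where(np.arange(24) == 5, 100.0, 0.0))


class TestBootstrapDifference:
    def test_null_case_no_signal(self, rng):
        counts = rng.poisson(5.0, size=(150, 24)).astype(float)
        diff = bootstrap_difference(counts, counts.copy(), n_replicates=2000, seed=3)
        assert np.abs(diff.median).max() < 0.3
        assert diff.significant.sum() <= 2  # ~5% false positives expected

    def test_swapping_cohorts_negates_the_median(self, rng):
        a = rng.poisson(4.0, size=(60, 24)).astype(float)
        b = rng.poisson(6.0, size=(80, 24)).astype(float)
        fwd = bootstrap_difference(a, b, n_replicates=4000, seed=4)
        rev = bootstrap_difference(b, a, n_replicates=4000, seed=4)
        # antisymmetric up to Monte-Carlo error (resampling streams differ)
        assert np.abs(fwd.median + rev.median).max() < 0.25

    def test_significance_flag_matches_ci(self, rng):
        a = rng.poisson(4.0, size=(50, 24)).astype(float)
        b = rng.poisson(4.0, size=(50, 24)).astype(float)
        diff = bootstrap_difference(a, b, n_replicates=1000, seed=5)
        assert np.array_equal(
            diff.significant, (diff.lower95 > 0) | (diff.upper95 < 0)
        )


class TestRelativeDifference:
    def test_identical_profiles_give_unit_ratios(self):
        prof = np.full(24, 100 / 24)
        assert relative_difference(prof, prof) == pytest.approx(np.ones(24))

    def test_arithmetic(self):
        a = np.full(24, 100 / 24)
        b = a.copy()
        a[21], b[21] = 5.5, 5.0
        assert relative_difference(a, b)[21] == pytest.approx(1.1)

    def test_zero_denominator_names_the_hour(self):
        b = np.full(24, 100 / 24)
        b[7] = 0.0
        with pytest.raises(UndefinedRatioError, match="7"):
            relative_difference(np.full(24, 100 / 24), b)


class TestPhaseShift:
    def test_identical_profiles_peak_at_lag_zero(self, rng):
        prof = rng.random(24)
        result = cross_correlation_phase(prof, prof)
        assert result.best_lag == 0 and result.best_r == pytest.approx(1.0)

    @pytest.mark.parametrize("lag", range(-12, 13))
    def test_phase_recovery_for_every_integer_shift(self, lag, rng):
        prof = rng.random(24)
        shifted = np.roll(prof, lag)
        result = cross_correlation_phase(prof, shifted)
        # +12 and -12 are the same circular shift; the tie resolves to -12
        expected = -12 if lag == 12 else lag
        assert result.best_lag == expected
        assert result.best_r == pytest.approx(1.0)

    def test_plus_minus_twelve_are_equal_by_circularity(self, rng):
        a, b = rng.random(24), rng.random(24)
        result = cross_correlation_phase(a, b)
        assert result.correlation[0] == pytest.approx(result.correlation[-1])

    def test_brute_force_oracle_agreement(self, rng):
        # independent oracle: explicit index arithmetic, no np.roll
        a, b = rng.random(24), rng.random(24)
        result = cross_correlation_phase(a, b)
        for lag, r in zip(result.lags, result.correlation):
            shifted = [b[(h + lag) % 24] for h in range(24)]
            expected = np.corrcoef(a, shifted)[0, 1]
            assert r == pytest.approx(expected)

    def test_constant_profile_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            cross_correlation_phase(np.ones(24), np.arange(24.0))
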