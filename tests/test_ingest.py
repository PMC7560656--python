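"""Ingestion: readers, study filters, localization, matched sampling."""

import json
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import pytest

from circadia import (
    EventRecord,
    UserProfile,
    filter_events,
    localize_hour,
    matched_sample,
    matches_diagnosis_pattern,
    read_events,
    read_profiles,
    resolve_timezone,
)
from circadia.exceptions import FormatError, LocalizationError, MatchingError
from conftest import make_events, make_profiles

ROWS = [
    {
        "tweet_id": f"t{i}",
        "user_id": "u1",
        "created_at": f"2018-06-01T0{i}:00:00+00:00",
        "text": "hello",
        "is_retweet": False,
        "lang": "en",
    }
    for i in range(3)
]


class TestReaders:
    def test_wellformed_jsonl_yields_all_records_in_order(self, tmp_path):
        path = tmp_path / "e.jsonl"
        path.write_text("\n".join(json.dumps(r) for r in ROWS) + "\n")
        events, malformed = read_events(path)
        assert len(events) == 3 and malformed == 0
        assert list(events.tweet_id) == ["t0", "t1", "t2"]
        assert str(events.created_at.dt.tz) == "UTC"

    def test_naive_timestamp_row_is_skipped_and_counted(self, tmp_path):
        bad = dict(ROWS[0], created_at="2018-06-01T00:00:00")
        path = tmp_path / "e.jsonl"
        path.write_text(json.dumps(bad) + "\n" + json.dumps(ROWS[1]) + "\n")
        events, malformed = read_events(path)
        assert len(events) == 1 and malformed == 1

    def test_csv_and_jsonl_encodings_yield_identical_streams(self, tmp_path):
        jpath = tmp_path / "e.jsonl"
        jpath.write_text("\n".join(json.dumps(r) for r in ROWS) + "\n")
        cpath = tmp_path / "e.csv"
        pd.DataFrame(ROWS).to_csv(cpath, index=False)
        ev_j, _ = read_events(jpath)
        ev_c, _ = read_events(cpath)
        pd.testing.assert_frame_equal(ev_j, ev_c)

    def test_missing_required_column_names_it(self, tmp_path):
        row = {k: v for k, v in ROWS[0].items() if k != "lang"}
        path = tmp_path / "e.jsonl"
        path.write_text(json.dumps(row) + "\n")
        with pytest.raises(FormatError, match="lang"):
            read_events(path)

    def test_profile_roundtrip(self, tmp_path):
        path = tmp_path / "p.jsonl"
        path.write_text(
            json.dumps(
                {"user_id": "u1", "timezone": "UTC", "created_month": "2015-01", "cohort": "D"}
            )
            + "\n"
        )
        profiles, malformed = read_profiles(path)
        assert malformed == 0 and profiles.iloc[0].cohort == "D"

    def test_naive_event_record_rejected(self):
        with pytest.raises(FormatError):
            EventRecord("t", "u", datetime(2018, 6, 1), "x", False, "en")


class TestDiagnosisPattern:
    @pytest.mark.parametrize(
        "text, expected",
        [
            # the canonical self-report phrasing used to seed such cohorts
            ("Went to my doctor today and got officially diagnosed with major depression", True),
            ("I feel sad today", False),
            # prefix rule is deliberately broad; screening matches is a human step
            ("diagnosing my depressing playlist", True),
            ("my prediagnosis depression story", False),  # no letter->letter boundary
            ("DIAGNOSED with DEPRESSION", True),
            ("depression is hard", False),  # needs both prefixes
        ],
    )
    def test_prefix_rule(self, text, expected):
        assert matches_diagnosis_pattern(text) is expected


class TestFilterEvents:
    def test_each_rule_counted_once(self):
        events = pd.concat(
            [
                make_events([1], user_id="u1", is_retweet=True),
                make_events([2], user_id="u1", lang="es"),
                make_events([3], user_id="u1"),
                make_events([4, 5], user_id="u1"),
            ],
            ignore_index=True,
        )
        events.loc[2, "text"] = "diagnosed with depression last week"
        profiles = make_profiles(["u1"])
        kept, report = filter_events(events, profiles)
        assert len(kept) == 2
        assert report.retweet == 1 and report.non_english == 1 and report.diagnosis == 1
        assert report.removed + report.retained == len(events)

    def test_clean_input_is_identity_with_zero_counts(self):
        events = make_events(range(5))
        kept, report = filter_events(events, make_profiles(["u1"]))
        pd.testing.assert_frame_equal(kept, events)
        assert report.removed == 0 and report.retained == 5

    def test_user_without_resolvable_timezone_is_dropped(self):
        events = make_events([1, 2], user_id="u_no_tz")
        profiles = make_profiles(["u_no_tz"], timezone="Atlantis/Nowhere")
        kept, report = filter_events(events, profiles)
        assert kept.empty and report.no_timezone == 2

    def test_user_without_profile_is_dropped_and_counted(self):
        events = make_events([1], user_id="ghost")
        kept, report = filter_events(events, make_profiles(["u1"]))
        assert kept.empty and report.unknown_user == 1

    def test_filtering_is_idempotent(self, small_dataset):
        _, events, profiles = small_dataset
        once, r1 = filter_events(events, profiles)
        twice, r2 = filter_events(once, profiles)
        pd.testing.assert_frame_equal(once, twice)
        assert r2.removed == 0


class TestLocalization:
    def _event(self, iso):
        return EventRecord("t", "u", datetime.fromisoformat(iso), "x", False, "en")

    def _profile(self, tz):
        return UserProfile("u", tz, "2015-01")

    def test_fixed_offset(self):
        ev = self._event("2018-06-01T00:30:00+00:00")
        assert localize_hour(ev, self._profile("UTC-05:00")) == 19

    def test_iana_zone_respects_summer_dst(self):
        ev = self._event("2018-06-01T03:00:00+00:00")
        assert localize_hour(ev, self._profile("America/New_York")) == 23

    def test_iana_zone_respects_winter_offset(self):
        ev = self._event("2018-01-15T03:00:00+00:00")
        assert localize_hour(ev, self._profile("America/New_York")) == 22

    def test_localization_roundtrip_recovers_utc_hour(self):
        # fixed offset: shifting the local hour back by the offset recovers UTC
        for offset in (-8, -5, 0, 3, 11):
            tz = f"UTC{offset:+03d}:00"
            ev = self._event("2018-06-01T10:00:00+00:00")
            local = localize_hour(ev, self._profile(tz))
            assert (local - offset) % 24 == 10

    def test_unresolvable_zone_raises(self):
        with pytest.raises(LocalizationError):
            resolve_timezone("Not/AZone")


class TestMatchedSample:
    def _profiles(self, months_counts, prefix):
        rows = []
        for month, n in months_counts.items():
            for i in range(n):
                rows.append({"user_id": f"{prefix}_{month}_{i}", "timezone": "UTC",
                             "created_month": month, "cohort": None})
        return pd.DataFrame(rows)

    def test_exact_apportionment(self):
        ref = self._profiles({"2015-01": 2, "2015-02": 2}, "ref")
        cand = self._profiles({"2015-01": 10, "2015-02": 10}, "c")
        picked = matched_sample(cand, ref, target_n=4, seed=0)
        months = [u.split("_")[1] for u in picked]
        assert sorted(months) == ["2015-01", "2015-01", "2015-02", "2015-02"]

    def test_proportional_apportionment(self):
        ref = self._profiles({"2015-01": 3, "2015-02": 1}, "ref")
        cand = self._profiles({"2015-01": 20, "2015-02": 20}, "c")
        picked = matched_sample(cand, ref, target_n=8, seed=0)
        months = [u.split("_")[1] for u in picked]
        assert months.count("2015-01") == 6 and months.count("2015-02") == 2

    def test_deficient_month_raises_naming_it(self):
        ref = self._profiles({"2015-03": 2}, "ref")
        cand = self._profiles({"2015-01": 10}, "c")
        with pytest.raises(MatchingError, match="2015-03"):
            matched_sample(cand, ref, target_n=2, seed=0)

    def test_candidates_overlapping_reference_are_excluded(self):
        ref = self._profiles({"2015-01": 2}, "x")
        cand = pd.concat([ref, self._profiles({"2015-01": 5}, "c")], ignore_index=True)
        picked = matched_sample(cand, ref, target_n=2, seed=0)
        assert all(u.startswith("c_") for u in picked)

    def test_month_distribution_is_integer_optimal(self, rng):
        # chi-square distance of the selection cannot beat the largest-remainder
        # quotas, and the selection must realize exactly those quotas
        ref_counts = {"2015-01": 7, "2015-02": 5, "2015-03": 1}
        ref = self._profiles(ref_counts, "ref")
        cand = self._profiles({m: 50 for m in ref_counts}, "c")
        target = 10
        picked = matched_sample(cand, ref, target_n=target, seed=3)
        sel_counts = pd.Series([u.split("_")[1] for u in picked]).value_counts()
        total_ref = sum(ref_counts.values())
        # brute force: best integer apportionment by chi-square distance
        best = None
        for a in range(target + 1):
            for b in range(target + 1 - a):
                c = target - a - b
                dist = sum(
                    (x / target - ref_counts[m] / total_ref) ** 2
                    for x, m in zip((a, b, c), ref_counts)
                )
                best = dist if best is None else min(best, dist)
        got = sum(
            (sel_counts.get(m, 0) / target - ref_counts[m] / total_ref) ** 2
            for m in ref_counts
        )
        assert got == pytest.approx(best, abs=1e-12)
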