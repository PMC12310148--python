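from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from wearcomply import compliance as comp
from wearcomply._util import round_half_up
from wearcomply.compliance import (
    ComplianceConfig,
    ComplianceSummary,
    aggregate_group,
    combine_totals,
    compute_wear_mask,
    longest_true_run,
    score_day,
    score_night,
    score_participant,
    summarize_participant,
    trim_study_window,
)
from wearcomply.synth import SimConfig, generate_participant

from .conftest import grid_record, make_epochs, make_record, uniform_sleep
from .oracles import brute_longest_run, brute_worn_minute

CFG = ComplianceConfig()


def _summary(pid, group, cd, sd, cn=0, sn=0):
    return ComplianceSummary(
        participant_id=pid, group=group, compliant_days=cd, study_days=sd,
        compliant_nights=cn, study_nights=sn,
        day_rate_pct=round_half_up(100 * cd / sd),
        night_rate_pct=round_half_up(100 * cn / sn) if sn else None,
    )


class TestWearMask:
    def test_hr_only_minute_is_worn(self):
        mask = compute_wear_mask(make_epochs([("2024-01-05T10:00:00", 72, None)]))
        assert mask.iloc[0]

    def test_empty_minute_not_worn(self):
        mask = compute_wear_mask(make_epochs([("2024-01-05T10:00:00", None, None)]))
        assert not mask.iloc[0]

    def test_zero_steps_alone_not_worn(self):
        mask = compute_wear_mask(make_epochs([("2024-01-05T10:00:00", None, 0)]))
        assert not mask.iloc[0]

    def test_positive_steps_alone_worn(self):
        mask = compute_wear_mask(make_epochs([("2024-01-05T10:00:00", None, 5)]))
        assert mask.iloc[0]

    def test_gap_minutes_in_grid_not_worn(self):
        rows = [("2024-01-05T10:00:00", 72, None), ("2024-01-05T10:05:00", 72, None)]
        mask = compute_wear_mask(make_epochs(rows))
        assert len(mask) == 6
        assert mask.sum() == 2

    def test_matches_per_minute_oracle_on_simulated_days(self, clean_cohort):
        # >= 10 participant-days re-evaluated minute-by-minute
        checked_days = 0
        for rec in clean_cohort.records[:3]:
            norm = rec.normalized()
            mask = compute_wear_mask(norm.epochs)
            by_ts = {
                ts: (hr, st)
                for ts, hr, st in zip(
                    norm.epochs["timestamp"], norm.epochs["heart_rate"], norm.epochs["steps"]
                )
            }
            for ts, worn in mask.items():
                hr, st = by_ts.get(ts, (None, None))
                assert worn == brute_worn_minute(hr, st), ts
            checked_days += (mask.index[-1].date() - mask.index[0].date()).days + 1
        assert checked_days >= 10

    def test_equals_ground_truth_on_artifact_free_data(self, clean_cohort):
        for rec in clean_cohort.records:
            mask = compute_wear_mask(rec.epochs)
            truth = rec.truth_worn.reindex(mask.index)
            assert (mask == truth).all()

    def test_clip_mode_disagreement_only_on_worn_sedentary_minutes(self):
        from wearcomply.synth import inject_clip_mode

        cfg = SimConfig(
            seed=9, n_per_group={"acute-cardiac": 1}, study_days=4,
            charge_gap_minutes=0, clip_mode_prob=0.0,
        )
        rec = generate_participant("acute-cardiac", cfg, 0)
        day = rec.to_local(rec.stream_start).date() + dt.timedelta(days=2)
        clipped = inject_clip_mode(rec, {day})
        mask = compute_wear_mask(clipped.epochs)
        truth = rec.truth_worn.reindex(mask.index)
        disagree = mask.index[(mask != truth).to_numpy()]
        ep = clipped.epochs.set_index("timestamp")
        for ts in disagree:
            assert truth.loc[ts] and not mask.loc[ts]  # only missed wear, never invented
            assert ep.loc[ts, "steps"] == 0.0  # worn-sedentary with HR suppressed


class TestLongestRun:
    @given(hst.lists(hst.booleans(), max_size=300))
    @settings(max_examples=200, deadline=None)
    def test_matches_scan_oracle(self, values):
        assert longest_true_run(np.array(values, dtype=bool)) == brute_longest_run(values)


class TestTrim:
    def test_partial_edges_excluded(self):
        n = int((pd.Timestamp("2024-01-20T14:00") - pd.Timestamp("2024-01-01T09:00"))
                / pd.Timedelta(minutes=1)) + 1
        rec = grid_record("2024-01-01T09:00:00", n, np.ones(n, dtype=bool))
        window = trim_study_window(rec, CFG)
        study = window.study_days
        assert study[0] == dt.date(2024, 1, 2)
        assert study[-1] == dt.date(2024, 1, 19)
        assert len(study) == 18

    def test_edge_aligned_stream_not_trimmed(self):
        n = 3 * 1440  # 00:00 Jan 1 .. 23:59 Jan 3
        rec = grid_record("2024-01-01T00:00:00", n, np.ones(n, dtype=bool))
        window = trim_study_window(rec, CFG)
        assert all(window.day_in_window.values())
        assert len(window.study_days) == 3

    def test_first_night_excluded(self):
        n = 6 * 1440
        sleep = [
            uniform_sleep(f"2024-01-0{d}T23:00:00", f"2024-01-0{d+1}T06:00:00")
            for d in range(1, 6)
        ]
        rec = grid_record("2024-01-01T00:00:00", n, np.ones(n, dtype=bool), sleep=sleep)
        window = trim_study_window(rec, CFG)
        assert len(window.night_in_window) == 5
        assert len(window.study_nights) == 4
        assert not window.night_in_window[dt.date(2024, 1, 2)]

    def test_no_trim_flags(self):
        n = 1440 + 120  # partial second day
        rec = grid_record("2024-01-01T00:00:00", n, np.ones(n, dtype=bool))
        cfg = ComplianceConfig(trim_partial_edge_days=False)
        assert len(trim_study_window(rec, cfg).study_days) == 2


class TestScoreDay:
    def _day_record(self, worn_minutes):
        worn = np.zeros(1440, dtype=bool)
        worn[:worn_minutes] = True
        return grid_record("2024-01-05T00:00:00", 1440, worn)

    def test_600_minutes_is_compliant_inclusive(self):
        rec = self._day_record(600)
        mask = compute_wear_mask(rec.epochs)
        assert score_day(mask, [], dt.date(2024, 1, 5), CFG).compliant

    def test_599_minutes_noncompliant(self):
        rec = self._day_record(599)
        mask = compute_wear_mask(rec.epochs)
        day = score_day(mask, [], dt.date(2024, 1, 5), CFG)
        assert day.awake_worn_minutes == 599
        assert not day.compliant

    def test_sleep_period_subtracted(self):
        rec = self._day_record(1440)
        mask = compute_wear_mask(rec.epochs)
        sleep = [uniform_sleep("2024-01-05T01:00:00", "2024-01-05T09:00:00")]
        day = score_day(mask, sleep, dt.date(2024, 1, 5), CFG)
        assert day.awake_worn_minutes == 960
        assert day.compliant

    def test_cross_midnight_sleep_subtracted_minutewise(self):
        # sleep attributed to the next night still removes this date's minutes
        rec = self._day_record(1440)
        mask = compute_wear_mask(rec.epochs)
        sleep = [uniform_sleep("2024-01-05T23:00:00", "2024-01-06T07:00:00")]
        day = score_day(mask, sleep, dt.date(2024, 1, 5), CFG)
        assert day.awake_worn_minutes == 1440 - 60


class TestScoreNight:
    def _mask(self, worn):
        rec = grid_record("2024-01-05T22:00:00", len(worn), worn)
        return compute_wear_mask(rec.epochs)

    def test_exact_180_run_compliant(self):
        worn = np.zeros(480, dtype=bool)
        worn[10:190] = True
        period = uniform_sleep("2024-01-05T22:00:00", "2024-01-06T06:00:00")
        night = score_night(self._mask(worn), period, CFG)
        assert night.longest_worn_run_minutes == 180
        assert night.compliant

    def test_split_runs_not_continuous(self):
        worn = np.zeros(480, dtype=bool)
        worn[0:120] = True
        worn[130:250] = True  # 240 worn total, max run 120
        period = uniform_sleep("2024-01-05T22:00:00", "2024-01-06T06:00:00")
        night = score_night(self._mask(worn), period, CFG)
        assert night.longest_worn_run_minutes == 120
        assert not night.compliant

    def test_179_noncompliant(self):
        worn = np.zeros(480, dtype=bool)
        worn[0:179] = True
        period = uniform_sleep("2024-01-05T22:00:00", "2024-01-06T06:00:00")
        assert not score_night(self._mask(worn), period, CFG).compliant

    @pytest.mark.parametrize("seed", range(10))
    def test_random_masks_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        worn = rng.random(480) < rng.uniform(0.3, 0.95)
        period = uniform_sleep("2024-01-05T22:00:00", "2024-01-06T06:00:00")
        night = score_night(self._mask(worn), period, CFG)
        assert night.longest_worn_run_minutes == brute_longest_run(worn)

    def test_night_date_is_wake_date(self):
        worn = np.ones(480, dtype=bool)
        period = uniform_sleep("2024-01-05T22:00:00", "2024-01-06T06:00:00")
        assert score_night(self._mask(worn), period, CFG).night_date == dt.date(2024, 1, 6)


class TestSummarize:
    def test_rate_format_86_67(self):
        s = _summary("p", "acute-cardiac", 26, 30)
        assert s.day_rate_pct == 86.67

    def test_all_compliant_100(self):
        s = _summary("p", "acute-cardiac", 30, 30)
        assert s.day_rate_pct == 100.00

    def test_simulated_counts_match_recount(self, clean_cohort):
        for rec in clean_cohort.records[:3]:
            scored = score_participant(rec, CFG)
            s = scored.summary
            assert s.compliant_days == sum(
                d.compliant for d in scored.days if d.in_study_window
            )
            assert s.study_days == sum(d.in_study_window for d in scored.days)
            assert s.compliant_nights == sum(
                n.compliant for n in scored.nights if n.in_study_window
            )
            assert s.compliant_days <= s.study_days
            assert s.compliant_nights <= s.study_nights

    def test_no_study_days_returns_none(self, caplog):
        rec = grid_record("2024-01-05T08:00:00", 120, np.ones(120, dtype=bool))
        assert summarize_participant(rec, CFG) is None


class TestAggregate:
    def test_combined_totals_sum(self):
        a = aggregate_group([_summary("a", "acute-orthopedic", 160, 175)], "acute-orthopedic")
        b = aggregate_group([_summary("b", "acute-cardiac", 325, 429)], "acute-cardiac")
        totals = combine_totals([a, b])
        assert totals.compliant_days == 485
        assert totals.study_days == 604

    def test_single_participant_degenerate(self):
        stats = aggregate_group([_summary("a", "acute-cardiac", 9, 10)], "acute-cardiac")
        assert stats.median_day_rate == 90.0
        assert stats.range_day_rate == (90.0, 90.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="no summaries"):
            aggregate_group([], "acute-cardiac")

    @given(hst.lists(hst.integers(min_value=0, max_value=30), min_size=1, max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_median_matches_sort_and_index_oracle(self, counts):
        rows = [_summary(f"p{i}", "acute-cardiac", c, 30) for i, c in enumerate(counts)]
        stats = aggregate_group(rows, "acute-cardiac")
        ordered = sorted(counts)
        n = len(ordered)
        expected = (
            ordered[n // 2] if n % 2 else (ordered[n // 2 - 1] + ordered[n // 2]) / 2
        )
        assert stats.median_compliant_days == expected
        assert stats.range_compliant_days == (min(counts), max(counts))

    def test_group_totals_equal_sum_of_participants(self, clean_cohort):
        summaries = [summarize_participant(r, CFG) for r in clean_cohort.records]
        summaries = [s for s in summaries if s is not None]
        for group in ("acute-orthopedic", "acute-cardiac", "chronic-IIPT"):
            stats = aggregate_group(summaries, group)
            rows = [s for s in summaries if s.group == group]
            assert stats.totals.compliant_days == sum(s.compliant_days for s in rows)
            assert stats.totals.study_nights == sum(s.study_nights for s in rows)


class TestMonotonicity:
    @given(
        hst.integers(min_value=0, max_value=1439),
        hst.integers(min_value=0, max_value=1439),
    )
    @settings(max_examples=60, deadline=None)
    def test_adding_worn_minutes_never_unflips(self, k, extra):
        worn = np.zeros(1440, dtype=bool)
        worn[:k] = True
        more = worn.copy()
        more[: min(1440, k + extra)] = True
        rec1 = grid_record("2024-01-05T00:00:00", 1440, worn)
        rec2 = grid_record("2024-01-05T00:00:00", 1440, more)
        d1 = score_day(compute_wear_mask(rec1.epochs), [], dt.date(2024, 1, 5), CFG)
        d2 = score_day(compute_wear_mask(rec2.epochs), [], dt.date(2024, 1, 5), CFG)
        assert d2.awake_worn_minutes >= d1.awake_worn_minutes
        if d1.compliant:
            assert d2.compliant

    @given(hst.integers(min_value=1, max_value=1440))
    @settings(max_examples=30, deadline=None)
    def test_raising_threshold_never_adds_compliance(self, threshold):
        worn = np.zeros(1440, dtype=bool)
        worn[:700] = True
        rec = grid_record("2024-01-05T00:00:00", 1440, worn)
        mask = compute_wear_mask(rec.epochs)
        base = score_day(mask, [], dt.date(2024, 1, 5), ComplianceConfig(day_threshold_min=600))
        harder = score_day(
            mask, [], dt.date(2024, 1, 5),
            ComplianceConfig(day_threshold_min=max(600, threshold)),
        )
        if harder.compliant:
            assert base.compliant


class TestBruteForceToyRecords:
    @pytest.mark.parametrize("seed", range(5))
    def test_three_day_records_match_exhaustive_scoring(self, seed):
        # every classification on a <=3-day toy record vs per-minute brute force
        rng = np.random.default_rng(seed)
        n = 3 * 1440
        worn = rng.random(n) < 0.7
        sleep = [
            uniform_sleep("2024-01-01T23:00:00", "2024-01-02T07:00:00"),
            uniform_sleep("2024-01-02T23:30:00", "2024-01-03T06:30:00"),
        ]
        rec = grid_record("2024-01-01T00:00:00", n, worn, sleep=sleep)
        scored = score_participant(rec, CFG)

        grid = pd.date_range("2024-01-01T00:00:00", periods=n, freq="min")
        asleep = set()
        for p in sleep:
            t = p.start
            while t < p.end:
                asleep.add(t)
                t += pd.Timedelta(minutes=1)
        for day in scored.days:
            expected = sum(
                1 for ts, w in zip(grid, worn)
                if w and ts.date() == day.date and ts not in asleep
            )
            assert day.awake_worn_minutes == expected
            assert day.compliant == (expected >= 600)
        for night, period in zip(scored.nights, sleep):
            in_period = [
                w for ts, w in zip(grid, worn) if period.start <= ts < period.end
            ]
            assert night.longest_worn_run_minutes == brute_longest_run(in_period)
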