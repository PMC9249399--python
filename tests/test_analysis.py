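"""History analyses: active-version lookup, recruitment-length change,
outcome-change runs, and follow-up-corrected status counts."""

from __future__ import annotations

import pandas as pd
import pytest

from trialhist.analysis import (
    FollowupReference,
    FollowupSpec,
    STOPPED_STATUSES,
    followup_status,
    latest_status,
    outcome_change_runs,
    recruitment_change,
    stopped_fraction,
    version_active_at,
)
from trialhist.fixtures import SimConfig, simulate_histories
from trialhist.registry_model import (
    HistoryTable,
    Registry,
    TrialId,
    encode_nested,
)

from conftest import make_ctgov_record

T1 = "NCT00000001"
T2 = "NCT00000002"


def _table(*rows) -> HistoryTable:
    return HistoryTable(Registry.CTGOV, rows)


class TestVersionActiveAt:
    def setup_method(self):
        self.table = _table(
            make_ctgov_record(T1, 1, "2010-01-01"),
            make_ctgov_record(T1, 2, "2011-01-01"),
            make_ctgov_record(T1, 3, "2012-01-01"),
        )
        self.trial = TrialId(Registry.CTGOV, T1)

    def test_boundary_is_inclusive(self):
        active = version_active_at(self.table, self.trial, "2011-01-01")
        assert active.stamp.version_number == 2

    def test_before_first_version_is_none(self):
        assert version_active_at(self.table, self.trial,
                                 "2009-12-31") is None

    def test_absent_trial_is_none(self):
        other = TrialId(Registry.CTGOV, T2)
        assert version_active_at(self.table, other, "2015-01-01") is None

    def test_same_date_tie_later_row_wins(self):
        table = _table(
            make_ctgov_record(T1, 1, "2010-01-01", status="Recruiting"),
            make_ctgov_record(T1, 2, "2010-01-01", status="Completed"),
        )
        trial = TrialId(Registry.CTGOV, T1)
        active = version_active_at(table, trial, "2010-06-01")
        assert active.stamp.version_number == 2

    def test_monotone_in_query_date(self):
        trial = TrialId(Registry.CTGOV, T1)
        prev = 0
        for date in ("2010-06-01", "2011-06-01", "2012-06-01"):
            n = version_active_at(self.table, trial,
                                  date).stamp.version_number
            assert n >= prev
            prev = n


ONE_YEAR = FollowupSpec(years=1, reference=FollowupReference.LAUNCH_START)


class TestRecruitmentChange:
    def test_fifty_percent_extension(self):
        # launch: 200-day recruitment period; at follow-up: 300 days
        table = _table(
            make_ctgov_record(T1, 1, "2010-01-01", status="Recruiting",
                              start="2010-01-01", pcd="2010-07-20"),
            make_ctgov_record(T1, 2, "2010-06-01", status="Recruiting",
                              start="2010-01-01", pcd="2010-10-28"),
        )
        (change,) = recruitment_change(table, ONE_YEAR)
        assert change.length_at_launch == 200
        assert change.length_at_followup == 300
        assert change.percent_change == "50%"

    def test_unchanged_dates_are_zero_percent(self):
        table = _table(
            make_ctgov_record(T1, 1, "2010-01-01", status="Recruiting",
                              start="2010-01-01", pcd="2010-07-20"),
        )
        (change,) = recruitment_change(table, ONE_YEAR)
        assert change.percent_change == "0%"

    def test_never_recruiting_trial_excluded(self):
        table = _table(
            make_ctgov_record(T1, 1, "2010-01-01", status="Withdrawn",
                              start="2010-01-01", pcd="2010-07-20"),
        )
        assert recruitment_change(table, ONE_YEAR) == []

    def test_recruiting_without_dates_not_a_launch_version(self):
        table = _table(
            make_ctgov_record(T1, 1, "2010-01-01", status="Recruiting"),
            make_ctgov_record(T1, 2, "2010-03-01", status="Recruiting",
                              start="2010-01-01", pcd="2010-07-20"),
        )
        (change,) = recruitment_change(table, ONE_YEAR)
        assert change.length_at_launch == 200

    def test_versions_after_horizon_ignored(self):
        table = _table(
            make_ctgov_record(T1, 1, "2010-01-01", status="Recruiting",
                              start="2010-01-01", pcd="2010-07-20"),
            make_ctgov_record(T1, 2, "2012-06-01", status="Recruiting",
                              start="2010-01-01", pcd="2012-12-31"),
        )
        (change,) = recruitment_change(table, ONE_YEAR)
        # version 2 postdates launch_start + 1 year: not the follow-up view
        assert change.length_at_followup == 200


def _om(text: str) -> str:
    return encode_nested([{"section": "Primary Outcome Measures:",
                           "label": "Measure:", "content": text}])


class TestOutcomeChangeRuns:
    def test_runs_emit_first_row_of_each_run(self):
        table = _table(
            make_ctgov_record(T1, 1, "2010-01-01", outcomes=_om("A")),
            make_ctgov_record(T1, 2, "2010-02-01", outcomes=_om("A")),
            make_ctgov_record(T1, 3, "2010-03-01", outcomes=_om("B")),
            make_ctgov_record(T1, 4, "2010-04-01", outcomes=_om("A")),
        )
        events = outcome_change_runs(table)
        assert [e.version_date for e in events] == \
            ["2010-01-01", "2010-03-01", "2010-04-01"]
        assert [e.run_index for e in events] == [1, 2, 3]

    def test_identical_versions_are_one_event(self):
        table = _table(
            *(make_ctgov_record(T1, n, f"2010-0{n}-01",
                                outcomes=_om("stable"))
              for n in (1, 2, 3)))
        assert len(outcome_change_runs(table)) == 1

    def test_single_whitespace_difference_opens_a_run(self):
        table = _table(
            make_ctgov_record(T1, 1, "2010-01-01",
                              outcomes=_om("Overall survival")),
            make_ctgov_record(T1, 2, "2010-02-01",
                              outcomes=_om("Overall  survival")),
        )
        assert len(outcome_change_runs(table)) == 2

    def test_identical_outcomes_in_different_trials_not_merged(self):
        table = _table(
            make_ctgov_record(T1, 1, "2010-01-01", outcomes=_om("A")),
            make_ctgov_record(T2, 1, "2010-01-01", outcomes=_om("A")),
        )
        assert len(outcome_change_runs(table)) == 2

    @pytest.mark.parametrize("registry,seed",
                             [(Registry.CTGOV, 5), (Registry.DRKS, 6)])
    def test_event_count_matches_brute_force_oracle(self, registry, seed):
        """Events = 1 + number of adjacent-version inequalities, checked
        against a direct pairwise scan of the outcome encodings."""
        truth = simulate_histories(SimConfig(
            n_trials=40, registry=registry, seed=seed,
            version_count_range=(1, 6), p_outcome_edit=0.3,
            p_whitespace_edit=0.1))
        table = truth.records

        def key(row):
            if registry is Registry.DRKS:
                return (row.primary_outcomes, row.secondary_outcomes)
            return row.outcome_measures

        expected = 0
        for trial in table.trial_ids():
            rows = table.rows_for(trial)
            expected += 1 + sum(
                1 for a, b in zip(rows, rows[1:]) if key(a) != key(b))
        assert len(outcome_change_runs(table)) == expected

    def test_detects_exactly_the_planted_edit_set(self):
        truth = simulate_histories(SimConfig(
            n_trials=30, registry=Registry.DRKS, seed=9,
            version_count_range=(2, 6), p_outcome_edit=0.4,
            p_whitespace_edit=0.2))
        events = outcome_change_runs(truth.records)
        detected = {}
        for e in events:
            detected.setdefault(e.trial.value, []).append(e.version_date)
        for trial in truth.records.trial_ids():
            rows = truth.records.rows_for(trial)
            planted = truth.outcome_change_versions[trial.value]
            expected_dates = [rows[0].stamp.version_date] + [
                rows[v - 1].stamp.version_date for v in planted]
            assert detected[trial.value] == expected_dates

    def test_no_edits_means_one_event_per_trial(self):
        truth = simulate_histories(SimConfig(
            n_trials=20, registry=Registry.DRKS, seed=10,
            p_outcome_edit=0.0, p_whitespace_edit=0.0, p_date_edit=0.0))
        assert len(outcome_change_runs(truth.records)) == 20


FIVE_YEARS = FollowupSpec(years=5)
TODAY = "2022-01-05"


class TestFollowupStatus:
    def test_stopped_within_horizon_is_counted(self):
        table = _table(
            make_ctgov_record(T1, 1, "2016-01-01", status="Recruiting"),
            make_ctgov_record(T1, 2, "2020-01-01", status="Terminated"),
        )
        (status,) = followup_status(table, FIVE_YEARS, TODAY)
        assert status.stopped
        assert status.overall_status == "Terminated"

    def test_insufficient_followup_excluded(self):
        table = _table(
            make_ctgov_record(T1, 1, "2021-01-01", status="Recruiting"),
        )
        assert followup_status(table, FIVE_YEARS, TODAY) == []

    def test_stop_after_horizon_not_counted(self):
        table = _table(
            make_ctgov_record(T1, 1, "2014-01-01", status="Recruiting"),
            make_ctgov_record(T1, 2, "2020-06-01", status="Terminated"),
        )
        (status,) = followup_status(table, FIVE_YEARS, TODAY)
        assert not status.stopped
        assert status.overall_status == "Recruiting"
        assert latest_status(table, status.trial) == "Terminated"

    def test_calendar_year_arithmetic_leap_day(self):
        table = _table(
            make_ctgov_record(T1, 1, "2016-02-29", status="Recruiting"),
            # one calendar year later is 2017-02-28; a version on 03-01
            # is already outside the 1-year horizon
            make_ctgov_record(T1, 2, "2017-03-01", status="Terminated"),
        )
        (status,) = followup_status(table, FollowupSpec(years=1),
                                    "2022-01-01")
        assert status.overall_status == "Recruiting"

    def test_lengthening_followup_never_adds_trials(self):
        truth = simulate_histories(SimConfig(
            n_trials=60, registry=Registry.CTGOV, seed=21))
        short = {s.trial.value for s in followup_status(
            truth.records, FollowupSpec(years=1), TODAY)}
        long = {s.trial.value for s in followup_status(
            truth.records, FIVE_YEARS, TODAY)}
        assert long <= short

    def test_recovers_simulated_cohort_against_pandas_oracle(self):
        """On 200+ simulated trials, the horizon classification matches an
        independent pandas groupby pipeline over the long-format frame."""
        truth = simulate_histories(SimConfig(
            n_trials=220, registry=Registry.CTGOV, seed=33,
            version_count_range=(1, 8)))
        table = truth.records
        result = {s.trial.value: s.stopped
                  for s in followup_status(table, FIVE_YEARS, TODAY)}

        df = table.to_dataframe()
        df["version_date"] = pd.to_datetime(df["version_date"])
        expected = {}
        cutoff = pd.Timestamp(TODAY) - pd.DateOffset(years=5)
        for nctid, group in df.groupby("nctid", sort=False):
            group = group.sort_values("version_number")
            first = group["version_date"].min()
            if first > cutoff:
                continue
            horizon = first + pd.DateOffset(years=5)
            at_horizon = group[group["version_date"] <= horizon]
            status = at_horizon.iloc[-1]["overall_status"]
            expected[nctid] = status in STOPPED_STATUSES
        assert result == expected
        assert len(result) >= 100  # the cohort is not trivially excluded


class TestStoppedFraction:
    def test_sixteen_of_ninety_three(self):
        frac = stopped_fraction([True] * 16 + [False] * 77)
        assert (frac.n_stopped, frac.n_total, frac.percent) == (16, 93, 17.2)

    def test_none_stopped(self):
        assert stopped_fraction([False] * 10).percent == 0.0

    def test_ten_of_sixty_nine_rounds_half_up(self):
        # 10/69 = 14.4927...% — one-decimal round-half-up gives 14.5
        assert stopped_fraction([True] * 10 + [False] * 59).percent == 14.5

    def test_empty_cohort_is_undefined(self):
        with pytest.raises(ValueError):
            stopped_fraction([])
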