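"""Polite fetching, the download loop, Error-sentinel resume, cohorts."""

from __future__ import annotations

import pytest

from trialhist.acquisition import (
    DownloadOutcome,
    FetchPolicy,
    FixtureDirTransport,
    MappingTransport,
    PoliteFetcher,
    Transport,
    TransportError,
    download_history,
    fetch_page,
    read_cohort,
    resume_download,
)
from trialhist.registry_model import (
    Registry,
    SchemaError,
    TrialId,
    read_history_csv,
    write_history_csv,
)


class FakeClock:
    """Deterministic clock: time advances only via sleep()."""

    def __init__(self) -> None:
        self.now = 0.0
        self.sleeps: list[float] = []

    def time(self) -> float:
        return self.now

    def sleep(self, seconds: float) -> None:
        self.sleeps.append(seconds)
        self.now += seconds


class CountingTransport(Transport):
    """Fails the first *fail_times* calls per page, then serves *pages*."""

    def __init__(self, inner: Transport, fail_times: int = 0) -> None:
        self.inner = inner
        self.fail_times = fail_times
        self.calls: list[tuple] = []
        self._failures: dict[tuple, int] = {}

    def _maybe_fail(self, key) -> None:
        self.calls.append(key)
        n = self._failures.get(key, 0)
        if n < self.fail_times:
            self._failures[key] = n + 1
            raise TransportError(f"simulated failure for {key}")

    def get_index(self, trial):
        self._maybe_fail((trial.value, None))
        return self.inner.get_index(trial)

    def get_version(self, trial, version_number):
        self._maybe_fail((trial.value, version_number))
        return self.inner.get_version(trial, version_number)


class ExplodingTransport(Transport):
    """A transport that must never be called."""

    def get_index(self, trial):
        raise AssertionError("unexpected fetch")

    def get_version(self, trial, version_number):
        raise AssertionError("unexpected fetch")


class TestPolicy:
    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            FetchPolicy(min_delay_seconds=-1)
        with pytest.raises(ValueError):
            FetchPolicy(max_retries_per_page=-1)

    def test_outcome_consistency_enforced(self):
        with pytest.raises(ValueError):
            DownloadOutcome(complete=True, rows_written=5, error_rows=2)


class TestPoliteFetcher:
    def test_fixture_transport_returns_page(self, ctgov_truth,
                                            no_delay_policy):
        trial = ctgov_truth.records.trial_ids()[0]
        html = fetch_page(trial, no_delay_policy,
                          transport=ctgov_truth.as_transport())
        assert html == ctgov_truth.index_pages[trial.value]

    def test_failure_marker_after_exhausted_retries(self, ctgov_truth):
        trial = ctgov_truth.records.trial_ids()[0]
        transport = CountingTransport(ctgov_truth.as_transport(),
                                      fail_times=99)
        policy = FetchPolicy(min_delay_seconds=0, max_retries_per_page=3)
        assert fetch_page(trial, policy, transport=transport) is None
        assert len(transport.calls) == 3

    def test_min_delay_enforced_between_fetches(self, ctgov_truth):
        trial = ctgov_truth.records.trial_ids()[0]
        clock = FakeClock()
        policy = FetchPolicy(min_delay_seconds=5, max_retries_per_page=1)
        fetcher = PoliteFetcher(ctgov_truth.as_transport(), policy,
                                time_fn=clock.time, sleep_fn=clock.sleep)
        fetcher.fetch_index(trial)
        fetcher.fetch_version(trial, 1)
        fetcher.fetch_version(trial, 2)
        # two inter-request waits of the full delay (clock is frozen
        # otherwise), none before the first request
        assert clock.sleeps == [5.0, 5.0]


class TestDownload:
    def test_row_count_is_sum_of_version_counts(self, ctgov_truth,
                                                no_delay_policy):
        trials = ctgov_truth.records.trial_ids()[:2]
        table = download_history(trials, None, no_delay_policy,
                                 ctgov_truth.as_transport())
        expected = sum(len(ctgov_truth.records.rows_for(t))
                       for t in trials)
        assert len(table) == expected
        assert table.rows == [r for t in trials
                              for r in ctgov_truth.records.rows_for(t)]

    def test_empty_trial_list(self, no_delay_policy, tmp_path):
        out = tmp_path / "empty.csv"
        outcome = download_history([], out, no_delay_policy,
                                   MappingTransport({}, {}))
        assert outcome == DownloadOutcome(True, 0, 0)

    def test_failed_version_page_becomes_error_row(self, ctgov_truth,
                                                   no_delay_policy):
        trial = ctgov_truth.records.trial_ids()[0]
        pages = dict(ctgov_truth.rendered_pages)
        del pages[(trial.value, 1)]
        table = download_history([trial], None, no_delay_policy,
                                 MappingTransport(ctgov_truth.index_pages,
                                                  pages))
        assert table.rows[0].is_error
        assert table.rows[0].stamp.version_date is not None
        assert not any(r.is_error for r in table.rows[1:])

    def test_unwritable_out_path_fails_before_fetching(self, ctgov_truth,
                                                       no_delay_policy,
                                                       tmp_path):
        transport = CountingTransport(ctgov_truth.as_transport())
        with pytest.raises(OSError):
            download_history(ctgov_truth.records.trial_ids(),
                             tmp_path / "no_dir" / "x.csv",
                             no_delay_policy, transport)
        assert transport.calls == []

    def test_mixed_registries_rejected(self, ctgov_truth, drks_truth,
                                       no_delay_policy):
        trials = [ctgov_truth.records.trial_ids()[0],
                  drks_truth.records.trial_ids()[0]]
        with pytest.raises(ValueError):
            download_history(trials, None, no_delay_policy,
                             MappingTransport({}, {}))

    def test_fixture_dir_transport_round_trip(self, drks_truth,
                                              no_delay_policy, tmp_path):
        drks_truth.write(tmp_path)
        table = download_history(drks_truth.records.trial_ids(), None,
                                 no_delay_policy,
                                 FixtureDirTransport(tmp_path))
        assert table == drks_truth.records


class TestResume:
    def test_error_rows_refetched_to_convergence(self, ctgov_truth,
                                                 no_delay_policy,
                                                 tmp_path):
        trial = ctgov_truth.records.trial_ids()[0]
        pages = dict(ctgov_truth.rendered_pages)
        del pages[(trial.value, 2)]
        out = tmp_path / "hist.csv"
        outcome = download_history(
            ctgov_truth.records.trial_ids(), out, no_delay_policy,
            MappingTransport(ctgov_truth.index_pages, pages))
        assert not outcome.complete and outcome.error_rows == 1

        resumed = resume_download(out, no_delay_policy,
                                  ctgov_truth.as_transport())
        assert resumed.complete
        ref = tmp_path / "ref.csv"
        write_history_csv(ctgov_truth.records, ref)
        assert out.read_bytes() == ref.read_bytes()

    def test_no_error_rows_means_no_fetches_and_no_change(
            self, ctgov_truth, no_delay_policy, tmp_path):
        out = tmp_path / "hist.csv"
        write_history_csv(ctgov_truth.records, out)
        before = out.read_bytes()
        outcome = resume_download(out, no_delay_policy,
                                  ExplodingTransport())
        assert outcome.complete
        assert out.read_bytes() == before

    def test_still_failing_transport_keeps_error_row(self, ctgov_truth,
                                                     no_delay_policy,
                                                     tmp_path):
        trial = ctgov_truth.records.trial_ids()[0]
        pages = dict(ctgov_truth.rendered_pages)
        del pages[(trial.value, 1)]
        broken = MappingTransport(ctgov_truth.index_pages, pages)
        out = tmp_path / "hist.csv"
        download_history([trial], out, no_delay_policy, broken)
        outcome = resume_download(out, no_delay_policy, broken)
        assert not outcome.complete and outcome.error_rows == 1

    def test_failed_index_writes_placeholder_then_resumes(
            self, ctgov_truth, no_delay_policy, tmp_path):
        trial = ctgov_truth.records.trial_ids()[0]
        out = tmp_path / "hist.csv"
        download_history([trial], out, no_delay_policy,
                         MappingTransport({}, ctgov_truth.rendered_pages))
        table = read_history_csv(out)
        assert len(table.rows) == 1
        assert table.rows[0].is_error
        assert table.rows[0].stamp.version_date is None

        resumed = resume_download(out, no_delay_policy,
                                  ctgov_truth.as_transport())
        assert resumed.complete
        assert read_history_csv(out).rows == \
            ctgov_truth.records.rows_for(trial)

    def test_resume_converges_with_eventually_succeeding_transport(
            self, drks_truth, no_delay_policy, tmp_path):
        """Iterating resume over a flaky-then-healthy transport reaches the
        same file as one fully successful download."""
        flaky = CountingTransport(drks_truth.as_transport(), fail_times=1)
        out = tmp_path / "hist.csv"
        outcome = download_history(drks_truth.records.trial_ids(), out,
                                   no_delay_policy, flaky)
        for _ in range(5):
            if outcome.complete:
                break
            outcome = resume_download(out, no_delay_policy, flaky)
        assert outcome.complete
        ref = tmp_path / "ref.csv"
        write_history_csv(drks_truth.records, ref)
        assert out.read_bytes() == ref.read_bytes()


class TestCohorts:
    def test_ctgov_cohort_comma_delimited(self, tmp_path):
        path = tmp_path / "SearchResults.csv"
        path.write_text('Rank,"NCT Number",Title\n'
                        '1,NCT00000001,A\n'
                        '2,NCT00000002,B\n'
                        '3,NCT00000003,C\n')
        ids = read_cohort(path, Registry.CTGOV)
        assert [t.value for t in ids] == \
            ["NCT00000001", "NCT00000002", "NCT00000003"]

    def test_drks_cohort_semicolon_delimited(self, tmp_path):
        path = tmp_path / "trials.csv"
        path.write_text("drksId;title\nDRKS00000001;A\nDRKS00000002;B\n")
        ids = read_cohort(path, Registry.DRKS)
        assert [t.value for t in ids] == ["DRKS00000001", "DRKS00000002"]

    def test_duplicates_removed_keeping_first(self, tmp_path):
        path = tmp_path / "dups.csv"
        path.write_text("NCT Number\nNCT00000002\nNCT00000001\n"
                        "NCT00000002\n")
        ids = read_cohort(path, Registry.CTGOV)
        assert [t.value for t in ids] == ["NCT00000002", "NCT00000001"]

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("Some Column\nNCT00000001\n")
        with pytest.raises(SchemaError, match="NCT Number"):
            read_cohort(path, Registry.CTGOV)
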