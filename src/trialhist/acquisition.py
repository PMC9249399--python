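"""Polite acquisition of registry version histories.

The download loop is deliberately boring: for each trial, fetch the version
index, then every version page, parse each into a record and append it to
the history table — flushing per version when writing to disk, so a partial
file survives interruption. Failures never raise out of the loop; they are
encoded as "Error"-sentinel rows carrying enough identity (trial, version
number, version date) for :func:`resume_download` to delete and re-fetch
exactly those rows later.

Transport is injected so the loop runs identically against live registries
(:class:`HttpTransport`, best-effort: registry sites change) or a directory
of fixture pages (:class:`FixtureDirTransport`) in tests. Politeness —
minimum inter-request delay, bounded retries, robots.txt — lives in
:class:`PoliteFetcher`, with an injectable clock so delay behaviour is
testable without sleeping.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Union

from . import ctgov_parser, drks_parser
from .registry_model import (
    HistoryTable,
    Registry,
    SchemaError,
    TrialId,
    VersionRecord,
    VersionStamp,
    read_history_csv,
    rows_to_csv_text,
)

logger = logging.getLogger(__name__)


class TransportError(Exception):
    """A page could not be retrieved (network, server, robots refusal)."""


@dataclass(frozen=True)
class FetchPolicy:
    """Politeness settings for registry fetching.

    ``min_delay_seconds`` is enforced between consecutive requests through
    the same fetcher (the registries are browsed per-host). Retries are per
    page; ``max_retries_per_page`` is the total number of attempts made
    before a page is given up as failed.
    """

    min_delay_seconds: float = 5.0
    user_agent: str = "trialhist/0.1 (registry history research)"
    max_retries_per_page: int = 3
    respect_robots: bool = True

    def __post_init__(self) -> None:
        if self.min_delay_seconds < 0:
            raise ValueError("min_delay_seconds must be >= 0")
        if self.max_retries_per_page < 0:
            raise ValueError("max_retries_per_page must be >= 0")


@dataclass(frozen=True)
class DownloadOutcome:
    """Result of a bulk download: complete iff no Error-sentinel rows."""

    complete: bool
    rows_written: int
    error_rows: int

    def __post_init__(self) -> None:
        if self.complete != (self.error_rows == 0):
            raise ValueError("complete must equal (error_rows == 0)")


class Transport:
    """Source of registry pages. ``get_index``/``get_version`` return HTML
    text or raise :class:`TransportError`."""

    def get_index(self, trial: TrialId) -> str:
        raise NotImplementedError

    def get_version(self, trial: TrialId, version_number: int) -> str:
        raise NotImplementedError


class MappingTransport(Transport):
    """In-memory transport over pre-rendered pages (fixtures, tests)."""

    def __init__(self, index_pages: dict, version_pages: dict) -> None:
        self.index_pages = dict(index_pages)
        self.version_pages = dict(version_pages)

    def get_index(self, trial: TrialId) -> str:
        try:
            return self.index_pages[trial.value]
        except KeyError:
            raise TransportError(f"no index page for {trial.value}") from None

    def get_version(self, trial: TrialId, version_number: int) -> str:
        try:
            return self.version_pages[(trial.value, version_number)]
        except KeyError:
            raise TransportError(
                f"no version page for {trial.value} v{version_number}"
            ) from None


class FixtureDirTransport(Transport):
    """Transport over a directory of fixture pages.

    Layout: ``<id>_index.html`` and ``<id>_v<n>.html``, as written by the
    fixture generator.
    """

    def __init__(self, directory) -> None:
        self.directory = Path(directory)

    def _read(self, name: str) -> str:
        path = self.directory / name
        try:
            return path.read_text(encoding="utf-8")
        except OSError as exc:
            raise TransportError(f"cannot read {path}: {exc}") from exc

    def get_index(self, trial: TrialId) -> str:
        return self._read(f"{trial.value}_index.html")

    def get_version(self, trial: TrialId, version_number: int) -> str:
        return self._read(f"{trial.value}_v{version_number}.html")


class HttpTransport(Transport):
    """Best-effort live transport over stdlib urllib.

    Registry sites redesign their history pages from time to time; the URL
    patterns here target the classic ClinicalTrials.gov history viewer and
    the DRKS trial pages and may need adjustment. All offline work goes
    through the fixture transports instead.
    """

    def __init__(self, policy: FetchPolicy) -> None:
        self.policy = policy
        self._robots: dict[str, object] = {}

    def _url_index(self, trial: TrialId) -> str:
        if trial.registry is Registry.CTGOV:
            return ("https://classic.clinicaltrials.gov/ct2/history/"
                    f"{trial.value}")
        return f"https://drks.de/search/en/trial/{trial.value}/versions"

    def _url_version(self, trial: TrialId, version_number: int) -> str:
        if trial.registry is Registry.CTGOV:
            return ("https://classic.clinicaltrials.gov/ct2/history/"
                    f"{trial.value}?V_{version_number}")
        return (f"https://drks.de/search/en/trial/{trial.value}/version/"
                f"{version_number}")

    def _allowed(self, url: str) -> bool:
        if not self.policy.respect_robots:
            return True
        from urllib import robotparser
        from urllib.parse import urlsplit, urlunsplit

        host = urlsplit(url).netloc
        rp = self._robots.get(host)
        if rp is None:
            rp = robotparser.RobotFileParser()
            rp.set_url(urlunsplit(("https", host, "/robots.txt", "", "")))
            try:
                rp.read()
            except OSError:
                rp = None  # robots unreachable: do not block
            self._robots[host] = rp
        if rp is None:
            return True
        return rp.can_fetch(self.policy.user_agent, url)

    def _get(self, url: str) -> str:
        from urllib.request import Request, urlopen

        if not self._allowed(url):
            raise TransportError(f"robots.txt disallows {url}")
        req = Request(url, headers={"User-Agent": self.policy.user_agent})
        try:
            with urlopen(req, timeout=60) as resp:
                charset = resp.headers.get_content_charset() or "utf-8"
                return resp.read().decode(charset, errors="replace")
        except OSError as exc:
            raise TransportError(f"fetch failed for {url}: {exc}") from exc

    def get_index(self, trial: TrialId) -> str:
        return self._get(self._url_index(trial))

    def get_version(self, trial: TrialId, version_number: int) -> str:
        return self._get(self._url_version(trial, version_number))


class PoliteFetcher:
    """Wraps a transport with inter-request delay and bounded retries.

    Never raises for page failures: exhausted retries return None (the
    failure marker), and the caller encodes that as an Error-sentinel row.
    The clock (``time_fn``/``sleep_fn``) is injectable for tests.
    """

    def __init__(self, transport: Transport, policy: FetchPolicy,
                 time_fn: Callable[[], float] = time.monotonic,
                 sleep_fn: Callable[[float], None] = time.sleep) -> None:
        self.transport = transport
        self.policy = policy
        self._time = time_fn
        self._sleep = sleep_fn
        self._last_request: Optional[float] = None

    def _wait_turn(self) -> None:
        if self._last_request is not None:
            elapsed = self._time() - self._last_request
            remaining = self.policy.min_delay_seconds - elapsed
            if remaining > 0:
                self._sleep(remaining)
        self._last_request = self._time()

    def _attempt(self, fn: Callable[[], str], what: str) -> Optional[str]:
        attempts = max(1, self.policy.max_retries_per_page)
        for i in range(attempts):
            self._wait_turn()
            try:
                return fn()
            except TransportError as exc:
                logger.warning("fetch %s failed (attempt %d/%d): %s",
                               what, i + 1, attempts, exc)
        return None

    def fetch_index(self, trial: TrialId) -> Optional[str]:
        return self._attempt(lambda: self.transport.get_index(trial),
                             f"{trial.value} index")

    def fetch_version(self, trial: TrialId,
                      version_number: int) -> Optional[str]:
        return self._attempt(
            lambda: self.transport.get_version(trial, version_number),
            f"{trial.value} v{version_number}")


def fetch_page(url_or_trial, policy: FetchPolicy, *,
               transport: Transport,
               time_fn: Callable[[], float] = time.monotonic,
               sleep_fn: Callable[[float], None] = time.sleep,
               version_number: Optional[int] = None) -> Optional[str]:
    """Fetch one page politely; None (never an exception) on failure.

    Convenience wrapper over :class:`PoliteFetcher` for single-page use:
    with ``version_number`` fetches that version page, otherwise the index.
    """
    fetcher = PoliteFetcher(transport, policy, time_fn, sleep_fn)
    trial = (url_or_trial if isinstance(url_or_trial, TrialId)
             else TrialId.from_string(url_or_trial))
    if version_number is None:
        return fetcher.fetch_index(trial)
    return fetcher.fetch_version(trial, version_number)


def _parse_version(registry: Registry, html: str,
                   stamp: VersionStamp) -> VersionRecord:
    if registry is Registry.CTGOV:
        return ctgov_parser.parse_ctgov_version(html, stamp)
    return drks_parser.parse_drks_version(html, stamp)


def _error_record(registry: Registry, stamp: VersionStamp) -> VersionRecord:
    if registry is Registry.CTGOV:
        return ctgov_parser.error_record(stamp)
    return drks_parser.error_record(stamp)


def _parse_index(registry: Registry, html: str) -> list[str]:
    if registry is Registry.CTGOV:
        return ctgov_parser.parse_date_index(html)
    return drks_parser.parse_drks_history(html)


def fetch_version_dates(trial: TrialId, policy: FetchPolicy,
                        transport: Transport,
                        fetcher: Optional[PoliteFetcher] = None
                        ) -> Optional[list[str]]:
    """ISO dates of all archived versions for one trial, earliest first.

    None when the index cannot be fetched or parsed (failure marker).
    """
    fetcher = fetcher or PoliteFetcher(transport, policy)
    html = fetcher.fetch_index(trial)
    if html is None:
        return None
    try:
        return _parse_index(trial.registry, html)
    except Exception as exc:
        logger.warning("index parse failed for %s: %s", trial.value, exc)
        return None


def _download_trial(trial: TrialId, registry: Registry,
                    fetcher: PoliteFetcher,
                    policy: FetchPolicy) -> list[VersionRecord]:
    """All version records for one trial; Error rows on failure.

    A failed or unparseable date index yields a single whole-trial
    placeholder row (version 1, no date) so resume can retry the trial.
    """
    dates = fetch_version_dates(trial, policy, fetcher.transport, fetcher)
    if dates is None:
        return [_error_record(registry,
                              VersionStamp(trial, 1, None))]
    records = []
    for number, date in enumerate(dates, start=1):
        stamp = VersionStamp(trial, number, date)
        records.append(_fetch_one_version(registry, fetcher, stamp))
    return records


def _fetch_one_version(registry: Registry, fetcher: PoliteFetcher,
                       stamp: VersionStamp) -> VersionRecord:
    html = fetcher.fetch_version(stamp.trial, stamp.version_number)
    if html is None:
        return _error_record(registry, stamp)
    return _parse_version(registry, html, stamp)


def _count_errors(rows: Iterable[VersionRecord]) -> int:
    return sum(1 for r in rows if r.is_error)


def download_history(trials: list[TrialId],
                     out_path=None,
                     policy: FetchPolicy = FetchPolicy(),
                     transport: Optional[Transport] = None,
                     fetcher: Optional[PoliteFetcher] = None,
                     ) -> Union[DownloadOutcome, HistoryTable]:
    """Download the full version history for a cohort of trials.

    With ``out_path`` the history is streamed to CSV (header first, then one
    flushed row per version — a partial file survives interruption) and a
    :class:`DownloadOutcome` is returned; without it, the
    :class:`HistoryTable` itself is returned. All trials must belong to one
    registry. Network failures surface only as Error-sentinel rows.
    """
    if transport is None and fetcher is None:
        transport = HttpTransport(policy)
    if fetcher is None:
        fetcher = PoliteFetcher(transport, policy)

    registries = {t.registry for t in trials}
    if len(registries) > 1:
        raise ValueError("all trial ids must share one registry")
    registry = registries.pop() if registries else Registry.CTGOV

    out_fh = None
    if out_path is not None:
        try:
            out_fh = open(out_path, "w", newline="", encoding="utf-8")
        except OSError as exc:
            raise OSError(
                f"cannot write history CSV to {out_path!r}: {exc}"
            ) from exc

    rows: list[VersionRecord] = []
    try:
        if out_fh is not None:
            out_fh.write(rows_to_csv_text(registry, []))
            out_fh.flush()
        for trial in trials:
            logger.info("downloading history for %s", trial.value)
            for record in _download_trial(trial, registry, fetcher, policy):
                rows.append(record)
                if out_fh is not None:
                    out_fh.write(rows_to_csv_text(registry, [record],
                                                  header=False))
                    out_fh.flush()
    finally:
        if out_fh is not None:
            out_fh.close()

    errors = _count_errors(rows)
    if out_path is None:
        return HistoryTable(registry, rows)
    return DownloadOutcome(complete=errors == 0, rows_written=len(rows),
                           error_rows=errors)


def resume_download(out_path,
                    policy: FetchPolicy = FetchPolicy(),
                    transport: Optional[Transport] = None,
                    fetcher: Optional[PoliteFetcher] = None,
                    ) -> DownloadOutcome:
    """Re-fetch exactly the Error-sentinel rows of an existing history CSV.

    Rows marked "Error" are deleted and downloaded again: rows with a known
    version stamp are re-fetched individually; whole-trial placeholder rows
    (no version date) trigger a full re-download of that trial. Non-error
    rows are carried over untouched. With no Error rows the file is left
    as-is and no fetches are made.
    """
    table = read_history_csv(out_path)
    registry = table.registry
    error_rows = [r for r in table.rows if r.is_error]
    if not error_rows:
        return DownloadOutcome(complete=True, rows_written=len(table.rows),
                               error_rows=0)

    if transport is None and fetcher is None:
        transport = HttpTransport(policy)
    if fetcher is None:
        fetcher = PoliteFetcher(transport, policy)

    trial_order: dict[str, int] = {}
    for r in table.rows:
        trial_order.setdefault(r.stamp.trial.value, len(trial_order))
    keep = [r for r in table.rows if not r.is_error]
    new_rows: list[VersionRecord] = []
    redo_trials = {r.stamp.trial.value: r.stamp.trial for r in error_rows
                   if r.stamp.version_date is None}
    # whole-trial redo supersedes any per-version retries for that trial
    for trial in redo_trials.values():
        keep = [r for r in keep if r.stamp.trial.value != trial.value]
        new_rows.extend(_download_trial(trial, registry, fetcher, policy))
    for record in error_rows:
        if record.stamp.trial.value in redo_trials:
            continue
        new_rows.append(_fetch_one_version(registry, fetcher, record.stamp))

    merged_rows = sorted(
        keep + new_rows,
        key=lambda r: (trial_order.get(r.stamp.trial.value,
                                       len(trial_order)),
                       r.stamp.version_number))
    merged = HistoryTable(registry, merged_rows)
    from .registry_model import write_history_csv

    write_history_csv(merged, out_path)
    errors = _count_errors(merged.rows)
    return DownloadOutcome(complete=errors == 0,
                           rows_written=len(merged.rows), error_rows=errors)


def read_cohort(path, registry: Registry) -> list[TrialId]:
    """Trial ids from a registry search-export CSV.

    ClinicalTrials.gov exports are comma-delimited with an ``NCT Number``
    column; DRKS exports are semicolon-delimited with a ``drksId`` column.
    Ids are returned in file order, de-duplicated keeping first occurrence.
    """
    delimiter = "," if registry is Registry.CTGOV else ";"
    column = "NCT Number" if registry is Registry.CTGOV else "drksId"
    with open(path, "r", newline="", encoding="utf-8-sig") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None or column not in reader.fieldnames:
            raise SchemaError(
                f"cohort file {path!r} lacks required column {column!r}"
            )
        seen: dict[str, TrialId] = {}
        for row in reader:
            value = (row.get(column) or "").strip()
            if not value:
                continue
            if value not in seen:
                seen[value] = TrialId(registry, value)
    return list(seen.values())
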