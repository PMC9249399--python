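"""Analyses over registry version histories.

Three reusable computations on a :class:`~trialhist.registry_model.HistoryTable`:

* **Recruitment-length change** — for each trial, the planned recruitment
  period (primary completion minus study start) as stated when the trial
  first reported status "Recruiting", versus the period stated in the
  version active a fixed follow-up later; reported as an integer percent
  change.

* **Outcome-change detection** — run-length scan over the encoded outcome
  structures of consecutive versions. Because the encodings are canonical
  JSON of the page text, *any* byte-level difference (down to a single
  inserted space) opens a new run; the first version of each run is an
  outcome-change event. Deciding which events are substantive remains a
  human-curation step.

* **Follow-up-corrected status counts** — assessing every trial's status at
  a common horizon (e.g. 5 years after first registration) instead of at
  "now". Naive latest-status counts are biased by variable follow-up time:
  recently registered trials have had less time to be stopped. Trials with
  less history than the horizon are excluded; stops occurring after the
  horizon do not count.

Calendar arithmetic uses calendar-aware periods (one year later = same
month/day next year; Feb 29 + 1 year = Feb 28), not fixed 365-day spans.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

from dateutil.relativedelta import relativedelta

from .registry_model import (
    CtgovVersionRecord,
    DrksVersionRecord,
    HistoryTable,
    Registry,
    TrialId,
    VersionRecord,
)

#: Overall statuses counted as "stopped".
STOPPED_STATUSES = frozenset({"Suspended", "Terminated", "Withdrawn"})


class FollowupReference(Enum):
    """What the follow-up period is measured from."""

    LAUNCH_START = "launch_start"     # study start at recruitment launch
    FIRST_VERSION = "first_version"   # first registry-entry version date


@dataclass(frozen=True)
class FollowupSpec:
    """A calendar follow-up period (years and/or days) and its reference."""

    years: int = 0
    days: int = 0
    reference: FollowupReference = FollowupReference.FIRST_VERSION

    def __post_init__(self) -> None:
        if self.years < 0 or self.days < 0 or (self.years == 0
                                               and self.days == 0):
            raise ValueError("follow-up duration must be positive")

    def period(self) -> relativedelta:
        return relativedelta(years=self.years, days=self.days)


@dataclass(frozen=True)
class RecruitmentChange:
    """Per-trial recruitment-period lengths at launch and follow-up."""

    trial: TrialId
    length_at_launch: int
    length_at_followup: Optional[int]
    percent_change: Optional[str]


@dataclass(frozen=True)
class OutcomeChangeEvent:
    """First version of one run of identical outcome specifications."""

    trial: TrialId
    version_date: Optional[str]
    primary_outcomes: Optional[str]
    secondary_outcomes: Optional[str]
    run_index: int


@dataclass(frozen=True)
class FollowupStatus:
    """A trial's registry status at the common follow-up horizon."""

    trial: TrialId
    first_version_date: str
    status_version_date: Optional[str]
    overall_status: Optional[str]
    stopped: bool


@dataclass(frozen=True)
class StoppedFraction:
    n_stopped: int
    n_total: int
    percent: float  # rounded half-up to one decimal


def _date(value: str) -> dt.date:
    return dt.date.fromisoformat(value)


def _by_trial(history: HistoryTable):
    """(trial, rows) groups in table order; rows are version-sorted."""
    groups: dict[str, list[VersionRecord]] = {}
    trials: dict[str, TrialId] = {}
    for row in history.rows:
        key = row.stamp.trial.value
        trials.setdefault(key, row.stamp.trial)
        groups.setdefault(key, []).append(row)
    return [(trials[k], rows) for k, rows in groups.items()]


def version_active_at(history: HistoryTable, trial: TrialId,
                      date: str) -> Optional[VersionRecord]:
    """The registry-entry version active on *date* for *trial*.

    That is the latest version whose version date is on or before *date*
    (ties on the same date: the later row wins). None when the trial is
    absent or its first version postdates *date*.
    """
    active = None
    for row in history.rows:
        if row.stamp.trial.value != trial.value:
            continue
        if row.stamp.version_date is None:
            continue
        if row.stamp.version_date <= date:  # ISO strings sort correctly
            active = row
    return active


def recruitment_change(history: HistoryTable,
                       followup: FollowupSpec) -> list[RecruitmentChange]:
    """Change in planned recruitment-period length over a follow-up window.

    Launch dates are the study start and primary completion dates from the
    earliest version with overall status "Recruiting" and both dates
    reported; trials with no such version are excluded. Follow-up dates
    come from the latest version dated at most ``launch start + follow-up``
    with both dates reported. Lengths are day differences; the change is
    rendered as an integer percent string ("50%"). Trials whose follow-up
    version cannot be determined are retained with missing follow-up
    fields.
    """
    if history.registry is not Registry.CTGOV:
        raise ValueError("recruitment_change requires a "
                         "ClinicalTrials.gov history")
    out = []
    for trial, rows in _by_trial(history):
        launch = None
        for row in rows:
            if (row.overall_status == "Recruiting"
                    and row.study_start_date is not None
                    and row.primary_completion_date is not None):
                launch = row
                break
        if launch is None:
            continue
        launch_start = _date(launch.study_start_date.date)
        launch_pcd = _date(launch.primary_completion_date.date)
        length_launch = (launch_pcd - launch_start).days

        horizon = launch_start + followup.period()
        fup = None
        for row in rows:
            if (row.stamp.version_date is not None
                    and _date(row.stamp.version_date) <= horizon
                    and row.study_start_date is not None
                    and row.primary_completion_date is not None):
                fup = row  # keep last qualifying version
        if fup is None or length_launch == 0:
            out.append(RecruitmentChange(trial, length_launch, None, None))
            continue
        length_fup = (_date(fup.primary_completion_date.date)
                      - _date(fup.study_start_date.date)).days
        pct = round(100 * length_fup / length_launch - 100)
        out.append(RecruitmentChange(trial, length_launch, length_fup,
                                     f"{pct}%"))
    return out


def _outcome_key(row: VersionRecord) -> tuple:
    if isinstance(row, DrksVersionRecord):
        return (row.stamp.trial.value, row.primary_outcomes,
                row.secondary_outcomes)
    # ClinicalTrials.gov analog: the single merged outcome-measures column
    return (row.stamp.trial.value, row.outcome_measures, None)


def outcome_change_runs(history: HistoryTable) -> list[OutcomeChangeEvent]:
    """Outcome-change events: the first version of each run of versions
    with byte-identical outcome encodings.

    Runs are computed over (trial id, primary outcomes, secondary outcomes)
    in row order — for ClinicalTrials.gov histories the merged
    outcome-measures column stands in for the primary slot. A trial's first
    version always opens a run, and any byte-level difference between
    adjacent versions (even one whitespace character) opens a new one.
    """
    events = []
    prev_key = None
    run_index = 0
    for row in history.rows:
        key = _outcome_key(row)
        if key != prev_key:
            run_index += 1
            if isinstance(row, DrksVersionRecord):
                primary, secondary = row.primary_outcomes, \
                    row.secondary_outcomes
            else:
                primary, secondary = row.outcome_measures, None
            events.append(OutcomeChangeEvent(
                trial=row.stamp.trial,
                version_date=row.stamp.version_date,
                primary_outcomes=primary,
                secondary_outcomes=secondary,
                run_index=run_index,
            ))
            prev_key = key
    return events


def followup_status(history: HistoryTable, followup: FollowupSpec,
                    today: str) -> list[FollowupStatus]:
    """Each trial's status in the version active at the follow-up horizon.

    The horizon is ``first version date + follow-up``. Trials first
    registered later than ``today − follow-up`` have not accrued the
    requisite follow-up and are excluded. The active version is the latest
    one dated at or before the horizon (same-date ties: later row wins);
    status changes after the horizon are invisible by construction.
    """
    cutoff = _date(today) - followup.period()
    out = []
    for trial, rows in _by_trial(history):
        dated = [r for r in rows if r.stamp.version_date is not None]
        if not dated:
            continue
        first = min(r.stamp.version_date for r in dated)
        if _date(first) > cutoff:
            continue
        horizon = _date(first) + followup.period()
        active = None
        for row in dated:
            if _date(row.stamp.version_date) <= horizon:
                active = row
        if active is None:
            continue
        status = (active.overall_status
                  if isinstance(active, CtgovVersionRecord)
                  else active.recruitment_status)
        out.append(FollowupStatus(
            trial=trial,
            first_version_date=first,
            status_version_date=active.stamp.version_date,
            overall_status=status,
            stopped=status in STOPPED_STATUSES,
        ))
    return out


def latest_status(history: HistoryTable, trial: TrialId) -> Optional[str]:
    """The status on the most recent version of *trial* (the naive view)."""
    rows = [r for r in history.rows if r.stamp.trial.value == trial.value]
    if not rows:
        return None
    last = rows[-1]
    return (last.overall_status if isinstance(last, CtgovVersionRecord)
            else last.recruitment_status)


def stopped_fraction(
    statuses: Sequence[Union[FollowupStatus, bool]]
) -> StoppedFraction:
    """Stopped trials as a fraction of the cohort.

    Accepts :class:`FollowupStatus` records or plain stopped flags. The
    percentage is rounded half-up to one decimal (16 of 93 → 17.2). Empty
    input is undefined and raises ``ValueError`` rather than returning 0.
    """
    flags = [s.stopped if isinstance(s, FollowupStatus) else bool(s)
             for s in statuses]
    if not flags:
        raise ValueError("stopped_fraction is undefined for an empty cohort")
    n_stopped = sum(flags)
    n_total = len(flags)
    percent = float(
        (Decimal(100 * n_stopped) / Decimal(n_total))
        .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )
    return StoppedFraction(n_stopped=n_stopped, n_total=n_total,
                           percent=percent)
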