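"""Shared fixtures: seeded synthetic registry histories and record builders."""

from __future__ import annotations

import pytest

from trialhist.acquisition import FetchPolicy
from trialhist.fixtures import SimConfig, simulate_histories
from trialhist.registry_model import (
    ApproxDate,
    CtgovVersionRecord,
    DatePrecision,
    Registry,
    TrialId,
    VersionStamp,
)


@pytest.fixture(scope="session")
def no_delay_policy() -> FetchPolicy:
    return FetchPolicy(min_delay_seconds=0.0, max_retries_per_page=1)


@pytest.fixture(scope="session")
def ctgov_truth():
    """Small ClinicalTrials.gov fixture set for unit tests."""
    return simulate_histories(
        SimConfig(n_trials=15, registry=Registry.CTGOV, seed=11))


@pytest.fixture(scope="session")
def drks_truth():
    """Small DRKS fixture set for unit tests."""
    return simulate_histories(
        SimConfig(n_trials=15, registry=Registry.DRKS, seed=12))


@pytest.fixture(scope="session")
def ctgov_truth_large():
    """100-trial ClinicalTrials.gov fixture set (round-trip invariants)."""
    return simulate_histories(
        SimConfig(n_trials=100, registry=Registry.CTGOV, seed=101))


@pytest.fixture(scope="session")
def drks_truth_large():
    """100-trial DRKS fixture set (round-trip invariants)."""
    return simulate_histories(
        SimConfig(n_trials=100, registry=Registry.DRKS, seed=102))


def make_ctgov_record(trial_value: str, number: int, version_date: str,
                      status: str = "Recruiting",
                      start: str | None = None,
                      pcd: str | None = None,
                      outcomes: str | None = None,
                      **kwargs) -> CtgovVersionRecord:
    """Minimal hand-built ClinicalTrials.gov version record."""
    trial = TrialId(Registry.CTGOV, trial_value)
    return CtgovVersionRecord(
        stamp=VersionStamp(trial, number, version_date),
        overall_status=status,
        study_start_date=(ApproxDate(start, DatePrecision.DAY)
                          if start else None),
        primary_completion_date=(ApproxDate(pcd, DatePrecision.DAY)
                                 if pcd else None),
        outcome_measures=outcomes,
        **kwargs,
    )
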