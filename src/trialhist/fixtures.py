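"""Synthetic registry histories with known ground truth.

The generator simulates trial registration histories — version dates,
status trajectories, enrolment and completion-date drift, outcome-measure
edits — and renders each version as registry-dialect HTML: labelled tables
with the classic ClinicalTrials.gov element ids, or DRKS-style bullet
lists. The rendered pages together with the ground-truth records make every
parser and analysis testable offline: parsing a rendered page must
reproduce the record it was rendered from, field for field.

What is emulated is the *parsed-element substructure* only (the tables,
bullets and text formats the extraction rules target), not registry page
chrome. Outcome edits come in two flavours, mirroring what change detection
must distinguish from noise: material edits (text appended to a measure)
and single-whitespace edits (one space inserted inside a measure, never at
the edges, where parsers would strip it).

Everything is driven by one seeded RNG: identical configurations produce
byte-identical pages.
"""

from __future__ import annotations

import datetime as dt
import html as html_mod
import random
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

from . import _css
from .acquisition import MappingTransport
from .registry_model import (
    ApproxDate,
    ConfigError,
    CtgovVersionRecord,
    DatePrecision,
    DrksVersionRecord,
    HistoryTable,
    Registry,
    TrialId,
    VersionStamp,
    decode_nested,
    encode_nested,
    write_history_csv,
)

#: Status vocabulary used for simulated ClinicalTrials.gov trials: the
#: stopped statuses plus common active states. A fixture vocabulary, not a
#: registry-complete list.
CTGOV_STATUSES = ("Recruiting", "Active not recruiting", "Completed",
                  "Terminated", "Suspended", "Withdrawn")

DRKS_STATUSES = ("Recruiting planned", "Recruiting ongoing",
                 "Recruiting complete", "Recruiting stopped")

_CTGOV_TRANSITIONS = {
    "Recruiting": {"Recruiting": 0.55, "Active not recruiting": 0.20,
                   "Completed": 0.10, "Terminated": 0.07,
                   "Suspended": 0.05, "Withdrawn": 0.03},
    "Active not recruiting": {"Active not recruiting": 0.60,
                              "Completed": 0.30, "Terminated": 0.10},
    "Suspended": {"Suspended": 0.50, "Recruiting": 0.20,
                  "Terminated": 0.30},
    "Completed": {"Completed": 1.0},
    "Terminated": {"Terminated": 1.0},
    "Withdrawn": {"Withdrawn": 1.0},
}

_DRKS_TRANSITIONS = {
    "Recruiting planned": {"Recruiting planned": 0.3,
                           "Recruiting ongoing": 0.6,
                           "Recruiting stopped": 0.1},
    "Recruiting ongoing": {"Recruiting ongoing": 0.6,
                           "Recruiting complete": 0.3,
                           "Recruiting stopped": 0.1},
    "Recruiting complete": {"Recruiting complete": 1.0},
    "Recruiting stopped": {"Recruiting stopped": 1.0},
}

_CONDITIONS = ("glioblastoma", "type 2 diabetes", "major depression",
               "chronic heart failure", "rheumatoid arthritis",
               "non small cell lung cancer", "atopic dermatitis")

_MEASURES = ("Overall survival", "Progression free survival",
             "Change in HbA1c", "MADRS total score",
             "Six minute walk distance", "DAS28 response",
             "EASI score improvement")

_SPONSORS = ("University Hospital A", "National Research Institute",
             "Midlands Medical Center", "Coastal Oncology Group")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the registry-history simulation.

    Edit probabilities are per version (from the second version on):
    ``p_outcome_edit`` a material outcome-text change, ``p_whitespace_edit``
    a single interior space insertion, ``p_date_edit`` a completion-date /
    enrolment drift. ``p_month_precision`` is the chance a simulated date is
    reported only to the month (ClinicalTrials.gov only).
    """

    n_trials: int = 100
    registry: Registry = Registry.CTGOV
    seed: int = 0
    version_count_range: tuple[int, int] = (1, 6)
    status_model: Optional[dict] = None
    p_outcome_edit: float = 0.2
    p_whitespace_edit: float = 0.05
    p_date_edit: float = 0.3
    p_month_precision: float = 0.3

    def __post_init__(self) -> None:
        lo, hi = self.version_count_range
        if lo < 1 or hi < lo:
            raise ConfigError("version_count_range lower bound must be >= 1 "
                              "and the range non-empty")
        if self.n_trials < 0:
            raise ConfigError("n_trials must be >= 0")
        for name in ("p_outcome_edit", "p_whitespace_edit", "p_date_edit",
                     "p_month_precision"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.status_model is not None:
            for state, probs in self.status_model.items():
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"transition probabilities for {state!r} sum to "
                        f"{total}, not 1")


@dataclass
class GroundTruth:
    """Simulated records plus their rendered registry pages.

    ``outcome_change_versions`` maps each trial id to the version numbers
    (>= 2) at which the encoded outcome structures differ from the previous
    version — the planted change set for detection tests.
    """

    records: HistoryTable
    rendered_pages: dict = field(default_factory=dict)  # (trial, n) -> html
    index_pages: dict = field(default_factory=dict)     # trial -> html
    outcome_change_versions: dict = field(default_factory=dict)

    def as_transport(self) -> MappingTransport:
        return MappingTransport(self.index_pages, self.rendered_pages)

    def write(self, out_dir) -> None:
        """Write index/version HTML files plus ``ground_truth.csv``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for trial, page in self.index_pages.items():
            (out / f"{trial}_index.html").write_text(page, encoding="utf-8")
        for (trial, number), page in self.rendered_pages.items():
            (out / f"{trial}_v{number}.html").write_text(page,
                                                         encoding="utf-8")
        write_history_csv(self.records, out / "ground_truth.csv")


def _step(rng: random.Random, transitions: dict, state: str) -> str:
    probs = transitions[state]
    r = rng.random()
    acc = 0.0
    for nxt, p in probs.items():
        acc += p
        if r <= acc:
            return nxt
    return nxt  # numerical slack: last state absorbs the remainder


def _insert_space(rng: random.Random, text: str) -> str:
    """Insert one space strictly inside *text* (never leading/trailing)."""
    if len(text) < 2:
        return text + " ."  # degenerate: force a visible change
    pos = rng.randint(1, len(text) - 1)
    return text[:pos] + " " + text[pos:]


def _month_name(month: int) -> str:
    return ("January", "February", "March", "April", "May", "June", "July",
            "August", "September", "October", "November",
            "December")[month - 1]


def _ctgov_date_text(ad: ApproxDate) -> str:
    d = dt.date.fromisoformat(ad.date)
    if ad.precision is DatePrecision.MONTH:
        return f"{_month_name(d.month)} {d.year}"
    return f"{_month_name(d.month)} {d.day}, {d.year}"


def _approx(rng: random.Random, date: dt.date,
            p_month: float) -> ApproxDate:
    if rng.random() < p_month:
        return ApproxDate(date.replace(day=1).isoformat(),
                          DatePrecision.MONTH)
    return ApproxDate(date.isoformat(), DatePrecision.DAY)


def _esc(text: str) -> str:
    return html_mod.escape(text, quote=False)


# ---------------------------------------------------------------------------
# simulation

def simulate_histories(config: SimConfig) -> GroundTruth:
    """Simulate trial histories and render them as registry HTML."""
    rng = random.Random(config.seed)
    if config.registry is Registry.CTGOV:
        truth = _simulate_ctgov(config, rng)
        pages = render_ctgov(truth)
    else:
        truth = _simulate_drks(config, rng)
        pages = render_drks(truth)
    for key, page in pages.items():
        trial, number = key
        if number is None:
            truth.index_pages[trial] = page
        else:
            truth.rendered_pages[(trial, number)] = page
    return truth


def _version_dates(rng: random.Random, count: int) -> list[str]:
    first = dt.date(2006, 1, 1) + dt.timedelta(days=rng.randint(0, 4000))
    dates = [first]
    for _ in range(count - 1):
        dates.append(dates[-1] + dt.timedelta(days=rng.randint(30, 400)))
    return [d.isoformat() for d in dates]


def _simulate_ctgov(config: SimConfig, rng: random.Random) -> GroundTruth:
    transitions = config.status_model or _CTGOV_TRANSITIONS
    ids = sorted(rng.sample(range(10 ** 8), config.n_trials))
    records = []
    change_versions: dict[str, list[int]] = {}
    for raw in ids:
        trial = TrialId(Registry.CTGOV, f"NCT{raw:08d}")
        n_versions = rng.randint(*config.version_count_range)
        dates = _version_dates(rng, n_versions)

        status = "Recruiting" if rng.random() < 0.9 \
            else "Active not recruiting"
        first_version = dt.date.fromisoformat(dates[0])
        start_date = first_version - dt.timedelta(days=rng.randint(0, 60))
        pcd = start_date + dt.timedelta(days=rng.randint(180, 1460))
        start = _approx(rng, start_date, config.p_month_precision)
        pcd_ad = _approx(rng, pcd, config.p_month_precision)
        pcd_type = "Anticipated"
        enrol_n = rng.randint(20, 500)
        min_age = str(rng.randint(18, 40))
        max_age = str(rng.randint(60, 99)) if rng.random() < 0.9 else None
        sex = rng.choice(("All", "Female", "Male"))
        gender_based = "No"
        healthy = rng.choice(("Yes", "No"))
        condition = rng.choice(_CONDITIONS)
        criteria_lines = [
            "Inclusion Criteria:",
            f"- adults with {condition}",
            "- able to give informed consent",
            "Exclusion Criteria:",
            "- prior enrolment in this study",
        ]
        outcomes = _base_ctgov_outcomes(rng)
        contacts = [
            {"label": "Contact:",
             "content": f"Study Coordinator, {rng.choice(_SPONSORS)}"},
        ]
        sponsors = [{"label": "Lead Sponsor:",
                     "content": rng.choice(_SPONSORS)}]

        change_versions[trial.value] = []
        for number, vdate in enumerate(dates, start=1):
            if number > 1:
                status = _step(rng, transitions, status)
                if rng.random() < config.p_date_edit:
                    pcd = pcd + dt.timedelta(days=rng.randint(30, 300))
                    pcd_ad = _approx(rng, pcd, config.p_month_precision)
                    enrol_n = max(1, enrol_n + rng.randint(-50, 80))
                if status == "Completed":
                    pcd_type = "Actual"
                changed = _maybe_edit_outcomes(rng, config, outcomes,
                                               number)
                if changed:
                    change_versions[trial.value].append(number)
            enrol_text = f"{enrol_n} [{pcd_type}]"
            records.append(CtgovVersionRecord(
                stamp=VersionStamp(trial, number, vdate),
                overall_status=status,
                enrolment=enrol_text,
                study_start_date=start,
                primary_completion_date=pcd_ad,
                primary_completion_date_type=pcd_type,
                min_age=min_age,
                max_age=max_age,
                sex=sex,
                gender_based=gender_based,
                accepts_healthy_volunteers=healthy,
                criteria=encode_nested(criteria_lines),
                outcome_measures=encode_nested(
                    [dict(r) for r in outcomes]),
                contacts=encode_nested([dict(r) for r in contacts]),
                sponsors=encode_nested([dict(r) for r in sponsors]),
            ))
    return GroundTruth(
        records=HistoryTable(Registry.CTGOV, records),
        outcome_change_versions=change_versions,
    )


def _base_ctgov_outcomes(rng: random.Random) -> list[dict]:
    primary = rng.choice(_MEASURES)
    secondary = rng.choice(_MEASURES)
    return [
        {"section": "Primary Outcome Measures:", "label": "Measure:",
         "content": primary},
        {"section": "Primary Outcome Measures:", "label": "Time Frame:",
         "content": f"{rng.randint(3, 36)} months"},
        {"section": "Secondary Outcome Measures:", "label": "Measure:",
         "content": secondary},
        {"section": "Secondary Outcome Measures:", "label": "Time Frame:",
         "content": f"{rng.randint(3, 60)} months"},
    ]


def _maybe_edit_outcomes(rng: random.Random, config: SimConfig,
                         outcomes: list[dict], version: int) -> bool:
    """Apply at most one outcome edit in place; True when anything changed.

    Material edits append a version-tagged amendment (guaranteed distinct);
    whitespace edits insert exactly one interior space.
    """
    content_rows = [r for r in outcomes if r["label"] != ""]
    if rng.random() < config.p_outcome_edit:
        row = rng.choice(content_rows)
        row["content"] = f"{row['content']} (amended v{version})"
        return True
    if rng.random() < config.p_whitespace_edit:
        row = rng.choice(content_rows)
        row["content"] = _insert_space(rng, row["content"])
        return True
    return False


def _simulate_drks(config: SimConfig, rng: random.Random) -> GroundTruth:
    transitions = config.status_model or _DRKS_TRANSITIONS
    ids = sorted(rng.sample(range(10 ** 8), config.n_trials))
    records = []
    change_versions: dict[str, list[int]] = {}
    for raw in ids:
        trial = TrialId(Registry.DRKS, f"DRKS{raw:08d}")
        n_versions = rng.randint(*config.version_count_range)
        dates = _version_dates(rng, n_versions)

        status = "Recruiting planned" if rng.random() < 0.5 \
            else "Recruiting ongoing"
        first_version = dt.date.fromisoformat(dates[0])
        start = first_version + dt.timedelta(days=rng.randint(0, 90))
        closing = start + dt.timedelta(days=rng.randint(180, 1200))
        enrol_n = rng.randint(20, 500)
        enrol_type = "Planned"
        min_age = f"{rng.randint(18, 40)} Years"
        max_age = ("no maximum age" if rng.random() < 0.3
                   else f"{rng.randint(60, 99)} Years")
        gender = rng.choice(("Male and female", "Female", "Male"))
        condition = rng.choice(_CONDITIONS)
        inclusion = [f"Adults with {condition}",
                     "Written informed consent"]
        exclusion = ["Pregnancy or breastfeeding",
                     "Participation in another interventional trial"]
        primary = [f"{rng.choice(_MEASURES)} at {rng.randint(3, 36)} weeks"]
        secondary = [f"{rng.choice(_MEASURES)} at {rng.randint(3, 60)} weeks",
                     "Quality of life score"]
        contacts = _base_drks_contacts(rng)

        change_versions[trial.value] = []
        for number, vdate in enumerate(dates, start=1):
            if number > 1:
                status = _step(rng, transitions, status)
                if rng.random() < config.p_date_edit:
                    closing = closing + dt.timedelta(
                        days=rng.randint(30, 300))
                    enrol_n = max(1, enrol_n + rng.randint(-50, 80))
                if status == "Recruiting complete":
                    enrol_type = "Actual"
                changed = _maybe_edit_drks_outcomes(
                    rng, config, primary, secondary, number)
                if changed:
                    change_versions[trial.value].append(number)
            records.append(DrksVersionRecord(
                stamp=VersionStamp(trial, number, vdate),
                recruitment_status=status,
                start_date=start.isoformat(),
                closing_date=closing.isoformat(),
                enrolment=enrol_n,
                enrolment_type=enrol_type,
                min_age=min_age,
                max_age=max_age,
                gender=gender,
                inclusion_criteria_additional=encode_nested(
                    list(inclusion)),
                exclusion_criteria=encode_nested(list(exclusion)),
                primary_outcomes=encode_nested(list(primary)),
                secondary_outcomes=encode_nested(list(secondary)),
                contacts=encode_nested([dict(c) for c in contacts]),
            ))
    return GroundTruth(
        records=HistoryTable(Registry.DRKS, records),
        outcome_change_versions=change_versions,
    )


def _base_drks_contacts(rng: random.Random) -> list[dict]:
    org = rng.choice(_SPONSORS)
    full = {
        "label": "Primary Sponsor",
        "affiliation": org,
        "telephone": f"+49 30 {rng.randint(1000, 9999)}",
        "fax": f"+49 30 {rng.randint(1000, 9999)}",
        "email": "study@example.org",
        "url": "https://example.org/trial",
    }
    if rng.random() < 0.3:  # sparse address: label + email only
        sparse = {"label": "Contact for Scientific Queries",
                  "affiliation": None, "telephone": None, "fax": None,
                  "email": "science@example.org", "url": None}
        return [full, sparse]
    return [full]


def _maybe_edit_drks_outcomes(rng: random.Random, config: SimConfig,
                              primary: list[str], secondary: list[str],
                              version: int) -> bool:
    target = primary if rng.random() < 0.5 else secondary
    idx = rng.randrange(len(target))
    if rng.random() < config.p_outcome_edit:
        target[idx] = f"{target[idx]} (amended v{version})"
        return True
    if rng.random() < config.p_whitespace_edit:
        target[idx] = _insert_space(rng, target[idx])
        return True
    return False


# ---------------------------------------------------------------------------
# rendering

_PAGE = ("<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
         "<title>{title}</title></head>\n<body>\n{body}\n</body></html>\n")


def render_ctgov(truth: GroundTruth) -> dict:
    """Render classic ClinicalTrials.gov pages for simulated records.

    Returns a mapping with ``(trial, None)`` keys for history-index pages
    (a "Submitted Date" column, one row per version) and ``(trial, n)``
    keys for version pages containing every extraction-table element.
    """
    pages: dict = {}
    table = truth.records
    if table.registry is not Registry.CTGOV:
        raise ValueError("render_ctgov requires ClinicalTrials.gov truth")
    for trial in table.trial_ids():
        rows = table.rows_for(trial)
        index_rows = "\n".join(
            f"<tr><td>{r.stamp.version_number}</td>"
            f"<td>{_esc(_ctgov_date_text(ApproxDate(r.stamp.version_date)))}"
            "</td></tr>"
            for r in rows)
        body = ("<table id=\"StudyVersions\">\n"
                "<tr><th>Version</th><th>Submitted Date</th></tr>\n"
                f"{index_rows}\n</table>")
        pages[(trial.value, None)] = _PAGE.format(
            title=f"{trial.value} history", body=body)
        for record in rows:
            pages[(trial.value, record.stamp.version_number)] = \
                _render_ctgov_version(record)
    return pages


def _render_ctgov_version(r: CtgovVersionRecord) -> str:
    status_rows = [f"<tr><td>Overall Status: {_esc(r.overall_status)}</td>"
                   "</tr>"]
    if r.study_start_date is not None:
        status_rows.append(
            "<tr><td>Study Start: "
            f"{_esc(_ctgov_date_text(r.study_start_date))}</td></tr>")
    if r.primary_completion_date is not None:
        text = _ctgov_date_text(r.primary_completion_date)
        if r.primary_completion_date_type:
            text += f" [{r.primary_completion_date_type}]"
        status_rows.append(
            f"<tr><td>Primary Completion: {_esc(text)}</td></tr>")

    elig_rows = []
    if r.min_age is not None:
        elig_rows.append(f"<tr><td>Minimum Age: {_esc(r.min_age)} Years"
                         "</td></tr>")
    if r.max_age is not None:
        elig_rows.append(f"<tr><td>Maximum Age: {_esc(r.max_age)} Years"
                         "</td></tr>")
    for label, value in (("Sex", r.sex), ("Gender Based", r.gender_based),
                         ("Accepts Healthy Volunteers",
                          r.accepts_healthy_volunteers)):
        if value is not None:
            elig_rows.append(f"<tr><td>{label}: {_esc(value)}</td></tr>")
    if r.criteria is not None:
        lines = "<br>".join(_esc(line)
                            for line in decode_nested(r.criteria))
        elig_rows.append(f"<tr><td>Criteria:</td><td>{lines}</td></tr>")

    outcome_rows = []
    if r.outcome_measures is not None:
        section = None
        for row in decode_nested(r.outcome_measures):
            if row["section"] != section:
                section = row["section"]
                outcome_rows.append(
                    f"<tr><td>{_esc(section)}</td><td></td></tr>")
            outcome_rows.append(
                f"<tr><td>{_esc(row['label'])}</td>"
                f"<td>{_esc(row['content'])}</td></tr>")

    contact_rows = []
    if r.contacts is not None:
        for row in decode_nested(r.contacts):
            contact_rows.append(
                f"<tr><td>{_esc(row['label'])}</td>"
                f"<td>{_esc(row['content'])}</td></tr>")
        contact_rows.append("<tr><td>Locations:</td><td></td></tr>")
        contact_rows.append("<tr><td>Facility:</td>"
                            "<td>Site 001, Example City</td></tr>")

    sponsor_rows = []
    if r.sponsors is not None:
        for row in decode_nested(r.sponsors):
            sponsor_rows.append(
                f"<tr><td>{_esc(row['label'])}</td>"
                f"<td>{_esc(row['content'])}</td></tr>")

    enrol_row = ("" if r.enrolment is None else
                 f"<tr><td>Enrollment: {_esc(r.enrolment)}</td></tr>")

    def table(el_id: str, rows: list[str], present: bool = True) -> str:
        # absent nested fields omit their table so they parse as missing
        if not present:
            return ""
        return (f"<table id=\"{el_id}\">\n" + "\n".join(rows)
                + "\n</table>")

    body = "\n".join(filter(None, (
        table("StudyStatusBody", status_rows),
        table("StudyDesignBody", [enrol_row]),
        table("EligibilityBody", elig_rows),
        table("ProtocolOutcomeMeasuresBody", outcome_rows,
              r.outcome_measures is not None),
        table("ContactsLocationsBody", contact_rows,
              r.contacts is not None),
        table("SponsorCollaboratorsBody", sponsor_rows,
              r.sponsors is not None),
    )))
    title = f"{r.stamp.trial.value} v{r.stamp.version_number}"
    return _PAGE.format(title=title, body=body)


def render_drks(truth: GroundTruth) -> dict:
    """Render DRKS.de-style pages: a change-history page with a "Date"
    column and bullet-list version pages, dates in ``YYYY/MM/DD``."""
    pages: dict = {}
    table = truth.records
    if table.registry is not Registry.DRKS:
        raise ValueError("render_drks requires DRKS truth")
    for trial in table.trial_ids():
        rows = table.rows_for(trial)
        index_rows = "\n".join(
            f"<tr><td>{r.stamp.version_number}</td>"
            f"<td>{r.stamp.version_date.replace('-', '/')}</td></tr>"
            for r in rows)
        body = ("<table class=\"versions\">\n"
                "<tr><th>Version</th><th>Date</th></tr>\n"
                f"{index_rows}\n</table>")
        pages[(trial.value, None)] = _PAGE.format(
            title=f"{trial.value} history", body=body)
        for record in rows:
            pages[(trial.value, record.stamp.version_number)] = \
                _render_drks_version(record)
    return pages


def _render_drks_version(r: DrksVersionRecord) -> str:
    bullets = [f"<li class=\"state\">Recruitment Status: "
               f"{_esc(r.recruitment_status)}</li>"]
    if r.start_date is not None:
        bullets.append(f"<li class=\"schedule\">Start Date: "
                       f"{r.start_date.replace('-', '/')}</li>")
    if r.closing_date is not None:
        bullets.append(f"<li class=\"deadline\">Closing Date: "
                       f"{r.closing_date.replace('-', '/')}</li>")
    if r.enrolment is not None:
        type_part = (f"; Planned/Actual: {_esc(r.enrolment_type)}"
                     if r.enrolment_type else "")
        bullets.append(f"<li class=\"targetSize\">Target Sample Size: "
                       f"{r.enrolment}{type_part}</li>")
    if r.min_age is not None:
        bullets.append(f"<li class=\"minAge\">Minimum Age: "
                       f"{_esc(r.min_age)}</li>")
    if r.max_age is not None:
        bullets.append(f"<li class=\"maxAge\">Maximum Age: "
                       f"{_esc(r.max_age)}</li>")
    if r.gender is not None:
        bullets.append(f"<li class=\"gender\">Gender: {_esc(r.gender)}</li>")

    def _lines_block(tag: str, cls: str, payload: Optional[str]) -> str:
        if payload is None:
            return ""
        lines = "<br>".join(_esc(line) for line in decode_nested(payload))
        return f"<{tag} class=\"{cls}\">{lines}</{tag}>"

    addresses = ""
    if r.contacts is not None:
        items = []
        for entry in decode_nested(r.contacts):
            subs = []
            if entry.get("affiliation"):
                subs.append(f"<li class=\"address-affiliation\">"
                            f"{_esc(entry['affiliation'])}</li>")
            for key, label in (("telephone", "Telephone:"), ("fax", "Fax:"),
                               ("email", "E-mail:"), ("url", "URL:")):
                if entry.get(key):
                    subs.append(
                        f"<li class=\"address-{key}\"><label>{label}"
                        f"</label> {_esc(entry[key])}</li>")
            label_html = (f"<label>{_esc(entry['label'])}</label>"
                          if entry.get("label") else "")
            items.append("<li class=\"address\">" + label_html
                         + "<ul>" + "".join(subs) + "</ul></li>")
        addresses = "<ul class=\"addresses\">" + "".join(items) + "</ul>"

    body = "\n".join(filter(None, (
        "<ul class=\"trial\">",
        "\n".join(bullets),
        "</ul>",
        _lines_block("div", "inclusionAdd",
                     r.inclusion_criteria_additional),
        _lines_block("div", "exclusion", r.exclusion_criteria),
        _lines_block("p", "primaryEndpoint", r.primary_outcomes),
        _lines_block("p", "secondaryEndpoints", r.secondary_outcomes),
        addresses,
    )))
    title = f"{r.stamp.trial.value} v{r.stamp.version_number}"
    return _PAGE.format(title=title, body=body)


# ---------------------------------------------------------------------------
# corruption

class CorruptionMode(Enum):
    TRUNCATE = "truncate"
    DROP_TABLE = "drop_table"
    BAD_DATE = "bad_date"


_CTGOV_DATE_TEXT = re.compile(r"[A-Z][a-z]+ [0-9]{1,2}, [0-9]{4}")
_SLASH_DATE_TEXT = re.compile(r"[0-9]{4}/[0-9]{2}/[0-9]{2}")


def corrupt_page(html: str, mode: CorruptionMode) -> str:
    """Damage a rendered page so the matching parser failure path fires.

    TRUNCATE cuts the document before any payload element (version parsers
    return the Error sentinel); DROP_TABLE removes the status element
    (missing-status path → Error sentinel); BAD_DATE rewrites the first
    date on an index page to unparseable text (index parse error).
    """
    if mode is CorruptionMode.TRUNCATE:
        return html[:120]
    if mode is CorruptionMode.DROP_TABLE:
        tree = _css.parse_html(html)
        for selector in ("#StudyStatusBody", "li.state"):
            for el in _css.select(tree, selector):
                el.getparent().remove(el)
        from lxml import html as lxml_html

        return lxml_html.tostring(tree, encoding="unicode")
    if mode is CorruptionMode.BAD_DATE:
        if _CTGOV_DATE_TEXT.search(html):
            return _CTGOV_DATE_TEXT.sub("Sometime 2010", html, count=1)
        return _SLASH_DATE_TEXT.sub("Sometime 2010", html, count=1)
    raise ValueError(f"unknown corruption mode: {mode!r}")
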