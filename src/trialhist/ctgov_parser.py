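"""Parsers for the classic ClinicalTrials.gov history pages.

Two document kinds are understood:

* the *history index* for one trial — a table of archived submissions with a
  "Submitted Date" column, one row per registry-entry version;
* a *version page* — the archived state of the record on one date, from which
  16 data points are extracted using CSS selectors plus regular expressions.

The selector/regex pairs live in one declarative table
(:data:`CTGOV_RULES`) so the extraction logic is data, not code: each rule
names the table element to search and the pattern whose first capture group
is the value. Table-structured fields (criteria, outcome measures, contacts,
sponsors) are parsed row-wise and encoded as canonical JSON instead.

``parse_ctgov_version`` is *total*: any input produces either a fully
populated record or the ``"Error"`` sentinel record, never an exception —
the download loop relies on this to keep going and mark rows for re-fetch.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass
from typing import Optional

from . import _css
from .registry_model import (
    ApproxDate,
    CtgovVersionRecord,
    DatePrecision,
    ERROR_SENTINEL,
    ParseError,
    ConfigError,
    VersionStamp,
    encode_nested,
)

logger = logging.getLogger(__name__)

#: Marker for fields parsed from table structure rather than a regex.
NESTED = "NESTED"


@dataclass(frozen=True)
class ExtractionRule:
    """One row of the extraction table: where to look and what to capture."""

    field_name: str
    css_selector: str
    regex: str  # pattern with at most one capture group, or NESTED

    def __post_init__(self) -> None:
        try:
            _css.css_to_xpath(self.css_selector)
        except _css.SelectorError as exc:
            raise ConfigError(str(exc)) from exc
        if self.regex != NESTED:
            try:
                compiled = re.compile(self.regex)
            except re.error as exc:
                raise ConfigError(
                    f"bad regex for {self.field_name}: {exc}"
                ) from exc
            if compiled.groups > 1:
                raise ConfigError(
                    f"regex for {self.field_name} has {compiled.groups} "
                    "capture groups; at most one is allowed"
                )

    @property
    def is_nested(self) -> bool:
        return self.regex == NESTED

    def pattern(self) -> "re.Pattern[str]":
        return re.compile(self.regex)


#: The ClinicalTrials.gov extraction table. Regex-extracted fields search the
#: text of cells inside the selected table element; first match in document
#: order wins.
CTGOV_RULES: dict[str, ExtractionRule] = {
    rule.field_name: rule
    for rule in (
        ExtractionRule("overall_status", "#StudyStatusBody",
                       r"Overall Status: ([A-Za-z, ]+)"),
        ExtractionRule("enrolment", "#StudyDesignBody",
                       r"Enrollment: ([A-Za-z0-9 \[\]]+)"),
        ExtractionRule("study_start_date", "#StudyStatusBody",
                       r"Study Start: ([A-Za-z0-9, ]+)"),
        ExtractionRule("primary_completion_date", "#StudyStatusBody",
                       r"Primary Completion: ([A-Za-z0-9, \[\]]+)"),
        ExtractionRule("primary_completion_date_type", "#StudyStatusBody",
                       r"(\[[A-Za-z]+\])"),
        ExtractionRule("min_age", "#EligibilityBody",
                       r"Minimum Age: ([0-9]+) Years"),
        ExtractionRule("max_age", "#EligibilityBody",
                       r"Maximum Age: ([0-9]+) Years"),
        ExtractionRule("sex", "#EligibilityBody",
                       r"Sex: ([A-Za-z]+)"),
        ExtractionRule("gender_based", "#EligibilityBody",
                       r"Gender Based: ([A-Za-z]+)"),
        ExtractionRule("accepts_healthy_volunteers", "#EligibilityBody",
                       r"Accepts Healthy Volunteers: ([A-Za-z]+)"),
        ExtractionRule("criteria", "#EligibilityBody", NESTED),
        ExtractionRule("outcome_measures", "#ProtocolOutcomeMeasuresBody",
                       NESTED),
        ExtractionRule("contacts", "#ContactsLocationsBody", NESTED),
        ExtractionRule("sponsors", "#SponsorCollaboratorsBody", NESTED),
    )
}


def _as_tree(html):
    if isinstance(html, str):
        return _css.parse_html(html)
    return html


def _cells(container) -> list:
    """All td/th cells under *container*, in document order."""
    return container.xpath(".//td|.//th")


def extract_field(html, rule: ExtractionRule) -> Optional[str]:
    """Apply a non-nested extraction rule to a document.

    Searches the text of every cell inside elements matched by the rule's
    selector (or the matched elements themselves if they contain no cells);
    the first regex match in document order wins. Returns the capture group,
    or the whole match for group-less patterns, or None when nothing matches.
    """
    if rule.is_nested:
        raise ValueError(f"{rule.field_name} is a nested field")
    tree = _as_tree(html)
    pattern = rule.pattern()
    for container in _css.select(tree, rule.css_selector):
        cells = _cells(container) or [container]
        for cell in cells:
            text = _css.element_text(cell)
            m = pattern.search(text)
            if m:
                return (m.group(1) if pattern.groups else m.group(0)).strip()
    return None


_MONTH_DAY_YEAR = re.compile(
    r"^([A-Z][a-z]+) ([0-9]{1,2}), ([0-9]{4})$"
)
_MONTH_YEAR = re.compile(r"^([A-Z][a-z]+) ([0-9]{4})$")

_MONTHS = {name: i for i, name in enumerate(
    ("January", "February", "March", "April", "May", "June", "July",
     "August", "September", "October", "November", "December"), start=1)}


def normalize_ctgov_date(text: str) -> ApproxDate:
    """Normalize a "Month Day, Year" or "Month Year" date to ISO-8601.

    Month-only dates are rounded to the first of the month and flagged with
    MONTH precision (e.g. "September 2009" → 2009-09-01, month); full dates
    keep DAY precision. Unrecognized text raises :class:`ParseError` with
    the original text preserved.
    """
    text = text.strip()
    m = _MONTH_DAY_YEAR.match(text)
    if m:
        month = _MONTHS.get(m.group(1))
        if month is None:
            raise ParseError(f"unrecognized date: {text!r}")
        date = dt.date(int(m.group(3)), month, int(m.group(2)))
        return ApproxDate(date.isoformat(), DatePrecision.DAY)
    m = _MONTH_YEAR.match(text)
    if m:
        month = _MONTHS.get(m.group(1))
        if month is None:
            raise ParseError(f"unrecognized date: {text!r}")
        date = dt.date(int(m.group(2)), month, 1)
        return ApproxDate(date.isoformat(), DatePrecision.MONTH)
    raise ParseError(f"unrecognized date: {text!r}")


def _find_column_table(tree, header_text: str):
    """Find (table, column index) for the table whose header row contains a
    cell with exactly *header_text*."""
    for table in tree.xpath("descendant-or-self::table"):
        for row in table.xpath(".//tr"):
            texts = [_css.element_text(c) for c in _cells(row)]
            if header_text in texts:
                return table, texts.index(header_text)
    return None, None


def parse_date_index(html) -> list[str]:
    """Version dates from a history-index page, earliest first.

    Reads every cell of the "Submitted Date" column of the study-record
    versions table, converts each to ISO-8601, and returns them sorted
    ascending (one date per registry version). Malformed input raises
    :class:`ParseError` rather than returning partial output.
    """
    tree = _as_tree(html)
    table, col = _find_column_table(tree, "Submitted Date")
    if table is None:
        raise ParseError("no study-record versions table with a "
                         "'Submitted Date' column")
    dates = []
    for row in table.xpath(".//tr"):
        cells = _cells(row)
        texts = [_css.element_text(c) for c in cells]
        if not cells or "Submitted Date" in texts:
            continue  # header row
        if col >= len(cells):
            continue
        text = texts[col]
        try:
            parsed = normalize_ctgov_date(text)
        except ParseError:
            raise ParseError(
                f"unparseable submitted date cell: {text!r}"
            ) from None
        if parsed.precision is not DatePrecision.DAY:
            raise ParseError(
                f"unparseable submitted date cell: {text!r}"
            )
        dates.append(parsed.date)
    if not dates:
        raise ParseError("study-record versions table has no date rows")
    return sorted(dates)


def parse_criteria(html) -> Optional[str]:
    """Eligibility criteria lines as a JSON array, or None when absent.

    The criteria live in the eligibility-table cell immediately following
    the cell labelled "Criteria:"; its text lines are preserved in order.
    """
    tree = _as_tree(html)
    body = _css.select_one(tree, "#EligibilityBody")
    if body is None:
        return None
    cells = _cells(body)
    for i, cell in enumerate(cells):
        if _css.element_text(cell) == "Criteria:":
            if i + 1 >= len(cells):
                return encode_nested([])
            return encode_nested(_css.text_lines(cells[i + 1]))
    return None


def parse_outcome_measures(html) -> Optional[str]:
    """Outcome-measure rows as JSON [{section, label, content}, ...].

    Section headings are table rows whose second cell contains no text; they
    are consumed as headers, and each data row's section is the text of the
    nearest preceding heading row.
    """
    tree = _as_tree(html)
    body = _css.select_one(tree, "#ProtocolOutcomeMeasuresBody")
    if body is None:
        return None
    rows = []
    section: Optional[str] = None
    for tr in body.xpath(".//tr"):
        cells = _cells(tr)
        if len(cells) < 2:
            continue
        label = _css.element_text(cells[0])
        content = _css.element_text(cells[1])
        if content == "":
            section = label
            continue
        rows.append({"section": section, "label": label, "content": content})
    return encode_nested(rows)


def parse_contacts(html) -> Optional[str]:
    """Contact rows as JSON [{label, content}, ...].

    Only rows strictly before the row labelled "Locations:" are contacts;
    that row and everything after it (the study sites) are excluded. When no
    "Locations:" row exists, all rows are included and a warning is logged.
    """
    tree = _as_tree(html)
    body = _css.select_one(tree, "#ContactsLocationsBody")
    if body is None:
        return None
    rows = []
    saw_divider = False
    for tr in body.xpath(".//tr"):
        cells = _cells(tr)
        if not cells:
            continue
        label = _css.element_text(cells[0])
        if label == "Locations:":
            saw_divider = True
            break
        content = _css.element_text(cells[1]) if len(cells) > 1 else ""
        rows.append({"label": label, "content": content})
    if not saw_divider:
        logger.warning("contacts table has no 'Locations:' divider; "
                       "including all rows")
    return encode_nested(rows)


def parse_sponsors(html) -> Optional[str]:
    """Sponsor/collaborator rows as JSON [{label, content}, ...]."""
    tree = _as_tree(html)
    body = _css.select_one(tree, "#SponsorCollaboratorsBody")
    if body is None:
        return None
    rows = []
    for tr in body.xpath(".//tr"):
        cells = _cells(tr)
        if not cells:
            continue
        label = _css.element_text(cells[0])
        content = _css.element_text(cells[1]) if len(cells) > 1 else ""
        rows.append({"label": label, "content": content})
    return encode_nested(rows)


_BRACKET_TOKEN = re.compile(r"\[[A-Za-z]+\]")


def error_record(stamp: VersionStamp) -> CtgovVersionRecord:
    """The sentinel record written when a version cannot be parsed."""
    return CtgovVersionRecord(stamp=stamp, overall_status=ERROR_SENTINEL)


def parse_ctgov_version(html, stamp: VersionStamp) -> CtgovVersionRecord:
    """Extract the 16 data points from one archived version page.

    Total function: unrecoverable failures (unparseable document, missing
    overall status, malformed dates) yield the "Error" sentinel record so a
    bulk download can continue and mark the row for re-fetch.
    """
    try:
        tree = _as_tree(html)
        status = extract_field(tree, CTGOV_RULES["overall_status"])
        if status is None:
            return error_record(stamp)

        start_raw = extract_field(tree, CTGOV_RULES["study_start_date"])
        start = normalize_ctgov_date(start_raw) if start_raw else None

        pcd_raw = extract_field(tree,
                                CTGOV_RULES["primary_completion_date"])
        pcd = None
        pcd_type = None
        if pcd_raw is not None:
            type_raw = extract_field(
                tree, CTGOV_RULES["primary_completion_date_type"])
            if type_raw is not None:
                pcd_type = type_raw.strip("[]")
            date_part = _BRACKET_TOKEN.sub("", pcd_raw).strip().rstrip(",")
            if date_part:
                pcd = normalize_ctgov_date(date_part)

        return CtgovVersionRecord(
            stamp=stamp,
            overall_status=status,
            enrolment=extract_field(tree, CTGOV_RULES["enrolment"]),
            study_start_date=start,
            primary_completion_date=pcd,
            primary_completion_date_type=pcd_type,
            min_age=extract_field(tree, CTGOV_RULES["min_age"]),
            max_age=extract_field(tree, CTGOV_RULES["max_age"]),
            sex=extract_field(tree, CTGOV_RULES["sex"]),
            gender_based=extract_field(tree, CTGOV_RULES["gender_based"]),
            accepts_healthy_volunteers=extract_field(
                tree, CTGOV_RULES["accepts_healthy_volunteers"]),
            criteria=parse_criteria(tree),
            outcome_measures=parse_outcome_measures(tree),
            contacts=parse_contacts(tree),
            sponsors=parse_sponsors(tree),
        )
    except Exception:
        logger.debug("version parse failed for %s v%s",
                     stamp.trial.value, stamp.version_number, exc_info=True)
        return error_record(stamp)
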