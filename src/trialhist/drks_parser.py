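"""Parsers for DRKS.de change-history and version pages.

DRKS (Deutsches Register Klinischer Studien) renders trial records as
bullet lists rather than labelled tables, so its extraction rules select
``li``/``p`` elements by class instead of table ids. Dates appear as
``YYYY/MM/DD`` and are normalized to ISO-8601 with hyphens; DRKS dates are
always day-precision (month rounding is a ClinicalTrials.gov concern).

13 data points are extracted per version. As for ClinicalTrials.gov, the
version parser is total: failure yields the "Error" sentinel record.
"""

from __future__ import annotations

import logging
import re
from typing import Optional

from . import _css
from .ctgov_parser import NESTED, ExtractionRule, _as_tree, _cells
from .registry_model import (
    DrksVersionRecord,
    ERROR_SENTINEL,
    ParseError,
    VersionStamp,
    encode_nested,
)

logger = logging.getLogger(__name__)

#: The DRKS.de extraction table (regex-extracted fields).
DRKS_RULES: dict[str, ExtractionRule] = {
    rule.field_name: rule
    for rule in (
        ExtractionRule("recruitment_status", "li.state",
                       r"Recruitment Status: ([A-Za-z, -]+)"),
        ExtractionRule("enrolment", "li.targetSize", r"[0-9]+"),
        ExtractionRule("enrolment_type", "li.targetSize",
                       r"Planned/Actual: ([A-Za-z]+)"),
        ExtractionRule("start_date", "li.schedule",
                       r"[0-9]{4}/[0-9]{2}/[0-9]{2}"),
        ExtractionRule("closing_date", "li.deadline",
                       r"[0-9]{4}/[0-9]{2}/[0-9]{2}"),
        ExtractionRule("min_age", "li.minAge",
                       r"Minimum Age: ([A-Za-z0-9 ]+)"),
        ExtractionRule("max_age", "li.maxAge",
                       r"Maximum Age: ([A-Za-z0-9 ]+)"),
        ExtractionRule("gender", "li.gender", r"Gender: ([A-Za-z ]+)"),
        ExtractionRule("inclusion_criteria_additional", ".inclusionAdd",
                       NESTED),
        ExtractionRule("exclusion_criteria", ".exclusion", NESTED),
        ExtractionRule("primary_outcomes", "p.primaryEndpoint", NESTED),
        ExtractionRule("secondary_outcomes", "p.secondaryEndpoints", NESTED),
        ExtractionRule("contacts", "ul.addresses li.address", NESTED),
    )
}

#: Selectors accepted by :func:`parse_drks_nested`.
NESTED_SELECTORS = (".inclusionAdd", ".exclusion",
                    "p.primaryEndpoint", "p.secondaryEndpoints")

_SLASH_DATE = re.compile(r"^[0-9]{4}/[0-9]{2}/[0-9]{2}$")


def _iso_from_slash(text: str) -> str:
    """``YYYY/MM/DD`` → ``YYYY-MM-DD``."""
    if not _SLASH_DATE.match(text):
        raise ParseError(f"not a YYYY/MM/DD date: {text!r}")
    return text.replace("/", "-")


def drks_extract(html, rule: ExtractionRule) -> Optional[str]:
    """Apply a non-nested DRKS rule: first matching element's text, first
    regex match wins; whole match for group-less patterns."""
    if rule.is_nested:
        raise ValueError(f"{rule.field_name} is a nested field")
    tree = _as_tree(html)
    pattern = rule.pattern()
    for el in _css.select(tree, rule.css_selector):
        text = _css.element_text(el)
        m = pattern.search(text)
        if m:
            return (m.group(1) if pattern.groups else m.group(0)).strip()
    return None


def parse_drks_history(html) -> list[str]:
    """Version dates from a DRKS change-history page, earliest first.

    Reads the "Date" column of the published-versions table; dates are
    normalized from the registry's ``YYYY/MM/DD`` form to ISO-8601 and
    returned sorted ascending (the page's own ordering is not relied on).
    """
    tree = _as_tree(html)
    from .ctgov_parser import _find_column_table

    table, col = _find_column_table(tree, "Date")
    if table is None:
        raise ParseError("no published-versions table with a 'Date' column")
    dates = []
    for row in table.xpath(".//tr"):
        cells = _cells(row)
        texts = [_css.element_text(c) for c in cells]
        if not cells or "Date" in texts:
            continue
        if col >= len(cells):
            continue
        text = texts[col]
        try:
            dates.append(_iso_from_slash(text))
        except ParseError:
            raise ParseError(
                f"unparseable version date cell: {text!r}"
            ) from None
    if not dates:
        raise ParseError("published-versions table has no date rows")
    return sorted(dates)


def parse_drks_nested(html, selector: str) -> Optional[str]:
    """Text lines of a nested DRKS element as a JSON array, or None.

    *selector* must be one of :data:`NESTED_SELECTORS`. Line order and
    internal whitespace are preserved (change detection depends on it).
    """
    if selector not in NESTED_SELECTORS:
        raise ValueError(f"unsupported nested selector: {selector!r}")
    tree = _as_tree(html)
    el = _css.select_one(tree, selector)
    if el is None:
        return None
    return encode_nested(_css.text_lines(el))


_ADDRESS_SUBFIELDS = (
    ("affiliation", "li.address-affiliation"),
    ("telephone", ".address-telephone"),
    ("fax", ".address-fax"),
    ("email", ".address-email"),
    ("url", ".address-url"),
)


def parse_drks_contacts(html) -> Optional[str]:
    """Address bullets as JSON [{label, affiliation, telephone, fax, email,
    url}, ...], or None when the addresses list is absent.

    The label comes from the bullet's ``<label>`` node; the other fields
    from their class-tagged sub-bullets, excluding each sub-bullet's own
    label text. Absent sub-fields are null.
    """
    tree = _as_tree(html)
    bullets = _css.select(tree, "ul.addresses li.address")
    if not bullets:
        return None
    entries = []
    for bullet in bullets:
        label_el = bullet.find("label")
        entry: dict[str, Optional[str]] = {
            "label": (_css.element_text(label_el)
                      if label_el is not None else None),
        }
        for key, selector in _ADDRESS_SUBFIELDS:
            el = _css.select_one(bullet, selector)
            if el is None:
                entry[key] = None
            else:
                text = _css.element_text_excluding(el,
                                                   frozenset({"label"}))
                entry[key] = text if text else None
        entries.append(entry)
    return encode_nested(entries)


def error_record(stamp: VersionStamp) -> DrksVersionRecord:
    """The sentinel record written when a version cannot be parsed."""
    return DrksVersionRecord(stamp=stamp, recruitment_status=ERROR_SENTINEL)


def parse_drks_version(html, stamp: VersionStamp) -> DrksVersionRecord:
    """Extract the 13 data points from one DRKS version page.

    Total function: unrecoverable failures yield the "Error" sentinel
    record so bulk downloads can continue.
    """
    try:
        tree = _as_tree(html)
        status = drks_extract(tree, DRKS_RULES["recruitment_status"])
        if status is None:
            return error_record(stamp)

        start_raw = drks_extract(tree, DRKS_RULES["start_date"])
        closing_raw = drks_extract(tree, DRKS_RULES["closing_date"])
        enrol_raw = drks_extract(tree, DRKS_RULES["enrolment"])

        return DrksVersionRecord(
            stamp=stamp,
            recruitment_status=status,
            start_date=_iso_from_slash(start_raw) if start_raw else None,
            closing_date=(_iso_from_slash(closing_raw)
                          if closing_raw else None),
            enrolment=int(enrol_raw) if enrol_raw is not None else None,
            enrolment_type=drks_extract(tree, DRKS_RULES["enrolment_type"]),
            min_age=drks_extract(tree, DRKS_RULES["min_age"]),
            max_age=drks_extract(tree, DRKS_RULES["max_age"]),
            gender=drks_extract(tree, DRKS_RULES["gender"]),
            inclusion_criteria_additional=parse_drks_nested(
                tree, ".inclusionAdd"),
            exclusion_criteria=parse_drks_nested(tree, ".exclusion"),
            primary_outcomes=parse_drks_nested(tree, "p.primaryEndpoint"),
            secondary_outcomes=parse_drks_nested(tree,
                                                 "p.secondaryEndpoints"),
            contacts=parse_drks_contacts(tree),
        )
    except Exception:
        logger.debug("version parse failed for %s v%s",
                     stamp.trial.value, stamp.version_number, exc_info=True)
        return error_record(stamp)
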