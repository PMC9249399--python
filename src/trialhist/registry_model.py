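"""Domain types and the long-format registry history table.

A clinical trial registry entry accumulates *versions*: each time the
responsible party edits the record, the registry archives the previous state.
The unit of exchange in this package is the :class:`HistoryTable` — a
long-format table with one registry-entry version per row — serialized as an
RFC 4180 CSV with a fixed, documented column order per registry.

Nested structures (inclusion criteria, outcome measures, contacts, sponsors)
are stored inside single CSV cells as *canonical JSON*: sorted keys, minimal
separators, no insignificant whitespace. Canonicality matters because change
detection downstream compares encoded outcome structures for byte equality —
two encodings are byte-equal exactly when the structures are equal.

Missing values are empty CSV cells, deliberately distinct from the literal
text ``"NA"`` which can occur in registry free text. The reserved status value
``"Error"`` marks a row whose download or parse failed; the acquisition layer
uses it to re-fetch exactly the failed rows on resume.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Optional, Union

logger = logging.getLogger(__name__)

#: Reserved status value marking a failed download/parse row.
ERROR_SENTINEL = "Error"

_ISO_DATE_RE = re.compile(r"^[0-9]{4}-[0-9]{2}-[0-9]{2}$")


class ParseError(ValueError):
    """A registry HTML document could not be interpreted."""


class SchemaError(ValueError):
    """A CSV file does not conform to the expected schema."""


class ConfigError(ValueError):
    """Invalid configuration (selectors, regexes, simulation parameters)."""


class Registry(Enum):
    """The two registry dialects understood by this package."""

    CTGOV = "ctgov"
    DRKS = "drks"


class DatePrecision(Enum):
    DAY = "day"
    MONTH = "month"


_ID_PATTERNS = {
    Registry.CTGOV: re.compile(r"^NCT[0-9]{8}$"),
    Registry.DRKS: re.compile(r"^DRKS[0-9]{8}$"),
}


@dataclass(frozen=True)
class TrialId:
    """Registry-qualified trial identifier (NCT number or DRKS id)."""

    registry: Registry
    value: str

    def __post_init__(self) -> None:
        if not _ID_PATTERNS[self.registry].match(self.value):
            raise ValueError(
                f"invalid {self.registry.name} trial id: {self.value!r}"
            )

    @classmethod
    def from_string(cls, value: str) -> "TrialId":
        """Infer the registry from the identifier prefix."""
        if value.startswith("NCT"):
            return cls(Registry.CTGOV, value)
        if value.startswith("DRKS"):
            return cls(Registry.DRKS, value)
        raise ValueError(f"unrecognized trial id: {value!r}")


def _check_iso_date(value: str, what: str) -> None:
    if not _ISO_DATE_RE.match(value):
        raise ValueError(f"{what} is not an ISO-8601 date: {value!r}")
    import datetime as _dt

    _dt.date.fromisoformat(value)  # raises on invalid calendar dates


@dataclass(frozen=True)
class VersionStamp:
    """Identity of one registry-entry version.

    ``version_number`` starts at 1 for the earliest archived version.
    ``version_date`` may be None only for whole-trial placeholder rows
    written when the version index itself could not be fetched.
    """

    trial: TrialId
    version_number: int
    version_date: Optional[str]

    def __post_init__(self) -> None:
        if self.version_number < 1:
            raise ValueError(
                f"version_number must be >= 1, got {self.version_number}"
            )
        if self.version_date is not None:
            _check_iso_date(self.version_date, "version_date")


@dataclass(frozen=True)
class ApproxDate:
    """A date that may be known only to month precision.

    Month-precision dates are rounded to the first of the month; the
    precision travels alongside so the rounding is recoverable.
    """

    date: str
    precision: DatePrecision = DatePrecision.DAY

    def __post_init__(self) -> None:
        _check_iso_date(self.date, "date")
        if self.precision is DatePrecision.MONTH and self.date[8:10] != "01":
            raise ValueError(
                f"month-precision date must fall on day 01: {self.date}"
            )


@dataclass(frozen=True)
class CtgovVersionRecord:
    """The 16 data points extracted from one ClinicalTrials.gov version.

    The data points are: overall status, enrolment, start date, start date
    precision, primary completion date, primary completion date precision,
    primary completion date type, minimum age, maximum age, sex, gender
    based, accepts healthy volunteers, inclusion criteria, outcome measures,
    contacts and sponsors. Date+precision pairs live in one
    :class:`ApproxDate` and serialize as two CSV columns.
    """

    stamp: VersionStamp
    overall_status: Optional[str] = None
    enrolment: Optional[str] = None
    study_start_date: Optional[ApproxDate] = None
    primary_completion_date: Optional[ApproxDate] = None
    primary_completion_date_type: Optional[str] = None
    min_age: Optional[str] = None
    max_age: Optional[str] = None
    sex: Optional[str] = None
    gender_based: Optional[str] = None
    accepts_healthy_volunteers: Optional[str] = None
    criteria: Optional[str] = None  # JSON list of criterion lines
    outcome_measures: Optional[str] = None  # JSON list of {section,label,content}
    contacts: Optional[str] = None  # JSON list of {label,content}
    sponsors: Optional[str] = None  # JSON list of {label,content}

    @property
    def is_error(self) -> bool:
        return self.overall_status == ERROR_SENTINEL


@dataclass(frozen=True)
class DrksVersionRecord:
    """The 13 data points extracted from one DRKS.de version.

    The data points are: recruitment status, start date, closing date,
    enrolment, enrolment type, minimum age, maximum age, gender, additional
    inclusion criteria, exclusion criteria, primary outcomes, secondary
    outcomes and contacts.
    """

    stamp: VersionStamp
    recruitment_status: Optional[str] = None
    start_date: Optional[str] = None
    closing_date: Optional[str] = None
    enrolment: Optional[int] = None
    enrolment_type: Optional[str] = None
    min_age: Optional[str] = None
    max_age: Optional[str] = None
    gender: Optional[str] = None
    inclusion_criteria_additional: Optional[str] = None  # JSON list of lines
    exclusion_criteria: Optional[str] = None  # JSON list of lines
    primary_outcomes: Optional[str] = None  # JSON list of lines
    secondary_outcomes: Optional[str] = None  # JSON list of lines
    contacts: Optional[str] = None  # JSON list of address mappings

    @property
    def is_error(self) -> bool:
        return self.recruitment_status == ERROR_SENTINEL


VersionRecord = Union[CtgovVersionRecord, DrksVersionRecord]

#: CSV column order, fixed per registry. The first three columns identify the
#: version; the remainder are the registry's data points.
CTGOV_COLUMNS = (
    "nctid",
    "version_number",
    "version_date",
    "overall_status",
    "enrolment",
    "study_start_date",
    "start_date_precision",
    "primary_completion_date",
    "primary_completion_date_precision",
    "primary_completion_date_type",
    "min_age",
    "max_age",
    "sex",
    "gender_based",
    "accepts_healthy_volunteers",
    "criteria",
    "outcome_measures",
    "contacts",
    "sponsors",
)

DRKS_COLUMNS = (
    "drksid",
    "version_number",
    "version_date",
    "recruitment_status",
    "start_date",
    "closing_date",
    "enrolment",
    "enrolment_type",
    "min_age",
    "max_age",
    "gender",
    "inclusion_criteria_additional",
    "exclusion_criteria",
    "primary_outcomes",
    "secondary_outcomes",
    "contacts",
)

COLUMNS_BY_REGISTRY = {
    Registry.CTGOV: CTGOV_COLUMNS,
    Registry.DRKS: DRKS_COLUMNS,
}

ID_COLUMN_BY_REGISTRY = {Registry.CTGOV: "nctid", Registry.DRKS: "drksid"}

#: Status column per registry — the column carrying the Error sentinel and
#: the trial-state vocabulary.
STATUS_COLUMN_BY_REGISTRY = {
    Registry.CTGOV: "overall_status",
    Registry.DRKS: "recruitment_status",
}


def encode_nested(rows) -> str:
    """Encode a nested structure as canonical JSON text.

    Canonical means: sorted keys, minimal separators, non-ASCII preserved.
    Byte equality of two encodings is then equivalent to structural equality,
    which is what outcome-change detection relies on. Raises ``TypeError``
    for non-serializable content.
    """
    return json.dumps(rows, sort_keys=True, separators=(",", ":"),
                      ensure_ascii=False)


def decode_nested(text: str):
    """Inverse of :func:`encode_nested`."""
    return json.loads(text)


class HistoryTable:
    """Long-format registry history: one registry-entry version per row.

    Rows are homogeneous per table (one registry) and kept grouped by trial,
    sorted by version number ascending within each trial. Trial groups keep
    their first-appearance order.
    """

    def __init__(self, registry: Registry,
                 rows: Iterable[VersionRecord] = ()) -> None:
        self.registry = registry
        self.rows: list[VersionRecord] = list(rows)
        self._normalize()

    def _normalize(self) -> None:
        expected = (CtgovVersionRecord if self.registry is Registry.CTGOV
                    else DrksVersionRecord)
        for row in self.rows:
            if not isinstance(row, expected):
                raise TypeError(
                    f"{self.registry.name} table cannot hold "
                    f"{type(row).__name__}"
                )
        order: dict[str, int] = {}
        for row in self.rows:
            order.setdefault(row.stamp.trial.value, len(order))
        self.rows.sort(key=lambda r: (order[r.stamp.trial.value],
                                      r.stamp.version_number))

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[VersionRecord]:
        return iter(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HistoryTable):
            return NotImplemented
        return self.registry is other.registry and self.rows == other.rows

    def __repr__(self) -> str:
        return (f"HistoryTable(registry={self.registry.name}, "
                f"n_rows={len(self.rows)})")

    def trial_ids(self) -> list[TrialId]:
        seen: dict[str, TrialId] = {}
        for row in self.rows:
            seen.setdefault(row.stamp.trial.value, row.stamp.trial)
        return list(seen.values())

    def rows_for(self, trial: TrialId) -> list[VersionRecord]:
        return [r for r in self.rows if r.stamp.trial.value == trial.value]

    def to_dataframe(self):
        """The table as a pandas DataFrame (missing values as None)."""
        import pandas as pd

        columns = COLUMNS_BY_REGISTRY[self.registry]
        data = [_record_to_cells(row, self.registry, raw=False)
                for row in self.rows]
        return pd.DataFrame(data, columns=list(columns))


def _approx_date_cells(value: Optional[ApproxDate]) -> tuple[str, str]:
    if value is None:
        return "", ""
    return value.date, value.precision.value


def _record_to_cells(row: VersionRecord, registry: Registry,
                     raw: bool = True):
    """Row cells in schema order. raw=True gives CSV strings ("" missing);
    raw=False gives native values (None missing) for DataFrame use."""

    def miss(v):
        if v is None:
            return "" if raw else None
        return str(v) if raw else v

    stamp = row.stamp
    if registry is Registry.CTGOV:
        start_d, start_p = _approx_date_cells(row.study_start_date)
        pcd_d, pcd_p = _approx_date_cells(row.primary_completion_date)
        cells = [
            stamp.trial.value,
            stamp.version_number if not raw else str(stamp.version_number),
            miss(stamp.version_date),
            miss(row.overall_status),
            miss(row.enrolment),
            start_d if raw else (start_d or None),
            start_p if raw else (start_p or None),
            pcd_d if raw else (pcd_d or None),
            pcd_p if raw else (pcd_p or None),
            miss(row.primary_completion_date_type),
            miss(row.min_age),
            miss(row.max_age),
            miss(row.sex),
            miss(row.gender_based),
            miss(row.accepts_healthy_volunteers),
            miss(row.criteria),
            miss(row.outcome_measures),
            miss(row.contacts),
            miss(row.sponsors),
        ]
    else:
        cells = [
            stamp.trial.value,
            stamp.version_number if not raw else str(stamp.version_number),
            miss(stamp.version_date),
            miss(row.recruitment_status),
            miss(row.start_date),
            miss(row.closing_date),
            miss(row.enrolment),
            miss(row.enrolment_type),
            miss(row.min_age),
            miss(row.max_age),
            miss(row.gender),
            miss(row.inclusion_criteria_additional),
            miss(row.exclusion_criteria),
            miss(row.primary_outcomes),
            miss(row.secondary_outcomes),
            miss(row.contacts),
        ]
    return cells


def record_from_mapping(registry: Registry, values: dict) -> VersionRecord:
    """Build a version record from a column-name → cell-text mapping."""

    def opt(name: str) -> Optional[str]:
        v = values.get(name, "")
        return v if v not in ("", None) else None

    trial = TrialId(registry, values[ID_COLUMN_BY_REGISTRY[registry]])
    stamp = VersionStamp(
        trial=trial,
        version_number=int(values["version_number"]),
        version_date=opt("version_date"),
    )
    if registry is Registry.CTGOV:
        def approx(date_col: str, prec_col: str) -> Optional[ApproxDate]:
            d = opt(date_col)
            if d is None:
                return None
            p = opt(prec_col) or "day"
            return ApproxDate(d, DatePrecision(p))

        return CtgovVersionRecord(
            stamp=stamp,
            overall_status=opt("overall_status"),
            enrolment=opt("enrolment"),
            study_start_date=approx("study_start_date",
                                    "start_date_precision"),
            primary_completion_date=approx(
                "primary_completion_date",
                "primary_completion_date_precision"),
            primary_completion_date_type=opt("primary_completion_date_type"),
            min_age=opt("min_age"),
            max_age=opt("max_age"),
            sex=opt("sex"),
            gender_based=opt("gender_based"),
            accepts_healthy_volunteers=opt("accepts_healthy_volunteers"),
            criteria=opt("criteria"),
            outcome_measures=opt("outcome_measures"),
            contacts=opt("contacts"),
            sponsors=opt("sponsors"),
        )
    enrol = opt("enrolment")
    return DrksVersionRecord(
        stamp=stamp,
        recruitment_status=opt("recruitment_status"),
        start_date=opt("start_date"),
        closing_date=opt("closing_date"),
        enrolment=int(enrol) if enrol is not None else None,
        enrolment_type=opt("enrolment_type"),
        min_age=opt("min_age"),
        max_age=opt("max_age"),
        gender=opt("gender"),
        inclusion_criteria_additional=opt("inclusion_criteria_additional"),
        exclusion_criteria=opt("exclusion_criteria"),
        primary_outcomes=opt("primary_outcomes"),
        secondary_outcomes=opt("secondary_outcomes"),
        contacts=opt("contacts"),
    )


def write_history_csv(table: HistoryTable, path) -> None:
    """Write *table* as an RFC 4180 CSV (UTF-8, CRLF, header row).

    Column order is fixed (:data:`CTGOV_COLUMNS` / :data:`DRKS_COLUMNS`);
    nested fields are stored as JSON strings; missing values are empty cells.
    Re-reading yields an equal table and re-writing a byte-identical file.
    """
    columns = COLUMNS_BY_REGISTRY[table.registry]
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(columns)
            for row in table.rows:
                writer.writerow(_record_to_cells(row, table.registry))
    except OSError as exc:
        raise OSError(f"cannot write history CSV to {path!r}: {exc}") from exc


def rows_to_csv_text(registry: Registry,
                     rows: Iterable[VersionRecord],
                     header: bool = True) -> str:
    """CSV text for *rows* (used for incremental append during download)."""
    buf = io.StringIO(newline="")
    writer = csv.writer(buf)
    if header:
        writer.writerow(COLUMNS_BY_REGISTRY[registry])
    for row in rows:
        writer.writerow(_record_to_cells(row, registry))
    return buf.getvalue()


def read_history_csv(path) -> HistoryTable:
    """Read a history CSV written by :func:`write_history_csv`.

    The registry is inferred from the identifier column in the header.
    Unknown extra columns are tolerated (with a logged warning); missing
    schema columns are a :class:`SchemaError` naming the offending column.
    """
    with open(path, "r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"empty history CSV: {path!r}") from None
        if "nctid" in header:
            registry = Registry.CTGOV
        elif "drksid" in header:
            registry = Registry.DRKS
        else:
            raise SchemaError(
                "history CSV lacks a trial id column "
                f"('nctid' or 'drksid'): {path!r}"
            )
        columns = COLUMNS_BY_REGISTRY[registry]
        for col in columns:
            if col not in header:
                raise SchemaError(
                    f"history CSV missing column {col!r}: {path!r}"
                )
        extra = [c for c in header if c not in columns]
        if extra:
            logger.warning("ignoring unknown columns %s in %r", extra, path)
        idx = {col: header.index(col) for col in columns}
        records = []
        for lineno, cells in enumerate(reader, start=2):
            if not cells:
                continue
            try:
                values = {col: cells[i] for col, i in idx.items()}
                records.append(record_from_mapping(registry, values))
            except (ValueError, IndexError) as exc:
                raise SchemaError(
                    f"bad history row at {path!r} line {lineno}: {exc}"
                ) from exc
    return HistoryTable(registry, records)
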