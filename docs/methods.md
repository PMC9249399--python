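# Methods

This note documents the data model, the extraction procedure, the three
analyses, the synthetic-data generator, and the numerical and design
choices behind them.

## The history table

The unit of analysis is a *registry entry version*: the state of one
trial's registry record as submitted on one date. A trial's history is the
ordered sequence of its versions; a cohort's history is a long-format
table with one version per row, grouped by trial and sorted by version
number (1 = earliest). The CSV serialization is RFC 4180, UTF-8, CRLF,
with a fixed column order:

* ClinicalTrials.gov — `nctid, version_number, version_date` followed by
  the 16 data points: `overall_status, enrolment, study_start_date,
  start_date_precision, primary_completion_date,
  primary_completion_date_precision, primary_completion_date_type,
  min_age, max_age, sex, gender_based, accepts_healthy_volunteers,
  criteria, outcome_measures, contacts, sponsors`.
* DRKS.de — `drksid, version_number, version_date` followed by the 13
  data points: `recruitment_status, start_date, closing_date, enrolment,
  enrolment_type, min_age, max_age, gender,
  inclusion_criteria_additional, exclusion_criteria, primary_outcomes,
  secondary_outcomes, contacts`.

The registries' field sets genuinely differ (DRKS has no sponsor table or
merged outcome-measures table; ClinicalTrials.gov has no closing date),
so the two record types are disjoint where the source data are.

Missing values are empty cells, deliberately distinct from the literal
text `NA`, which can occur in registry free text. The reserved status
value `Error` marks a row whose download or parse failed; it does not
collide with either registry's status vocabulary.

### Canonical JSON for nested structures

Inclusion criteria (a list of text lines), outcome measures (rows of
`{section, label, content}`), contacts and sponsors (`{label, content}`
rows; DRKS addresses with `{label, affiliation, telephone, fax, email,
url}`) are encoded into single CSV cells as JSON with **sorted keys and
minimal separators**. Canonicality is load-bearing: outcome-change
detection compares encodings for byte equality, so two encodings must be
byte-equal exactly when the structures are equal. For the same reason
parsers strip only leading/trailing whitespace of extracted text and
preserve internal whitespace byte-for-byte — a single inserted space is a
real, detectable change.

## Extraction

Each scalar field is specified by one row of a declarative extraction
table: a CSS selector naming the element to search and a regular
expression whose (single) capture group is the value; group-less patterns
(the DRKS enrolment integer and `YYYY/MM/DD` dates) yield the whole
match. Matching uses search semantics with no anchoring; the first
matching cell in document order wins. Selector/regex validity is checked
when the table is loaded (a configuration error), never at parse time.
Since the selector grammar used is tiny (`#id`, `tag.class`, descendant
chains), selectors are compiled to XPath by a small built-in translator
and evaluated with lxml.

ClinicalTrials.gov dates arrive as "Month Day, Year" or "Month Year";
both are normalized to ISO-8601. Month-only dates are rounded to day 01
and flagged `month` in the sibling precision column, so the rounding is
recoverable downstream. DRKS dates arrive as `YYYY/MM/DD` and are
normalized to hyphens; DRKS precision is always `day`. The
ClinicalTrials.gov primary-completion cell carries a bracketed type token
(`[Anticipated]`/`[Actual]`); it is captured separately and stored
without brackets, and is removed from the cell text before date parsing.

Structure-parsing rules:

* *Criteria* — the eligibility-table cell immediately following the cell
  labelled exactly `Criteria:`; its lines (split at `<br>`) in order.
  Absent label → missing; empty cell → `[]`.
* *Outcome measures* — table rows; a row whose second cell has no text is
  a section heading and is consumed, not emitted; each data row's
  `section` is the nearest preceding heading.
* *Contacts* — rows strictly before the `Locations:` row. If no
  `Locations:` row exists all rows are included and a warning logged
  (the absent divider is treated as no exclusion boundary).
* *DRKS addresses* — one entry per `ul.addresses li.address` bullet;
  sub-fields come from class-tagged sub-bullets with their own label text
  excluded; absent sub-fields are null.

The version parsers are **total**: any input produces either a complete
record (every data point present as a value or an explicit missing) or
the `Error` sentinel record. A missing status cell, an unparseable date,
or arbitrarily damaged HTML all take the sentinel path; nothing raises
out of a bulk download. If a version page happened to contain two status
tables, the first in document order would win.

## Acquisition, politeness, resume

Transport is injected: the same download loop runs against live HTTP
(stdlib urllib; robots.txt honored when `respect_robots` is set), an
in-memory page mapping, or a fixture directory. The fetch policy enforces
a minimum inter-request delay (default 5 s — a conservative choice, since
registries are designed for manual browsing) and a bounded number of
attempts per page (default 3). The clock is injectable, so delay
behaviour is tested without sleeping.

Rows are appended and flushed to the output CSV one version at a time, so
a partially written file survives interruption. A failed version page
becomes an `Error` row carrying its version stamp; a failed *index*
fetch becomes a single whole-trial placeholder row (version 1, no date).
`resume` deletes exactly the `Error` rows and re-fetches them — per
version when the stamp is known, the whole trial for placeholders —
leaving every other row untouched and preserving the file's trial order.
Iterated against an eventually-healthy source, resume converges to the
byte-identical file a fully successful download would have produced. The
download/resume return value (and the CLI exit code) encodes one bit:
complete ⇔ no `Error` rows remain.

## The analyses

**Recruitment-length change.** Launch dates are the study start and
primary completion dates of the *earliest* version with status
`Recruiting` and both dates reported (same-date ties: first row).
Follow-up dates come from the *latest* version dated at most
`launch start + Δ` with both dates reported (ties: last row). Lengths are
day differences; the report is `round(100·L_fup/L_launch − 100)` rendered
as an integer percent string, using banker's rounding (round-half-even)
for the integer percent. Trials never `Recruiting` with dates are
excluded; trials with a launch version but no qualifying follow-up
version are retained with missing follow-up fields (they carry
information — the trial existed — and dropping them silently would bias
any downstream completeness accounting). A zero-day launch period leaves
the percent missing rather than dividing by zero.

**Outcome-change runs.** The run key is (trial id, primary outcomes,
secondary outcomes) for DRKS; ClinicalTrials.gov has one merged
outcome-measures column, which stands in for the primary slot with the
secondary slot missing. Runs are maximal stretches of consecutive rows
with identical keys; each trial's first version opens a run, and the
first row of each run is emitted with a global 1-based run index. The
detector is deliberately maximally sensitive (byte equality); separating
typo fixes from outcome switching is a human-curation step by design.

**Follow-up correction.** For each trial the horizon is
`first version date + Δ`. The status is read from the latest version
dated at or before the horizon (same-date ties: last row). Trials with
`first version date > today − Δ` are excluded — they have not accrued the
requisite follow-up. Because the status is read *at the horizon*, stops
occurring after it are invisible, which is the point: a naive
latest-status count mixes 1-year-old and 10-year-old trials and is never
smaller than the corrected count on cohorts with late stops. Calendar
arithmetic uses calendar periods, not 365-day spans: one year after
2016-02-29 is 2017-02-28, and the same-month/same-day convention applies
throughout. The stopped set is {Suspended, Terminated, Withdrawn}.

The stopped fraction is reported to one decimal with round-half-up
(16/93 → 17.2%, 10/69 → 14.5%). Note 10/69 = 14.4927…%, so any
truncation-based convention would print 14.4 — this package documents and
uses round-half-up rather than matching a truncating convention.

## The synthetic-data generator

The generator's job is to produce registry histories with *known ground
truth* and render them in both registry dialects, so that
`parse(render(truth)) == truth` is checkable field-for-field and the
analyses can be validated against planted effects.

Per trial: a version count drawn from `version_count_range` (default 1–6,
matching the short histories typical of registered trials); strictly
increasing version dates (first version uniform over 2006–2016, gaps of
30–400 days); a status trajectory from a Markov model over {Recruiting,
Active not recruiting, Completed, Terminated, Suspended, Withdrawn} (a
fixture vocabulary: the stopped statuses plus common active states, not a
registry-complete list) with stopped and completed states absorbing;
eligibility, criteria, contacts and sponsors drawn from small fixed
vocabularies. Dates are month-precision with probability
`p_month_precision` (default 0.3, reflecting how commonly registry dates
are month-granular). Per version from the second on: with `p_date_edit`
(default 0.3) the completion date drifts 30–300 days later and enrolment
drifts; with `p_outcome_edit` (default 0.2) an outcome text gains a
version-tagged amendment (guaranteed distinct); failing that, with
`p_whitespace_edit` (default 0.05) exactly one space is inserted strictly
inside an outcome string — never at the edges, where parsers would strip
it and mask the edit. Planted edit versions are recorded in the ground
truth, so detection tests compare recovered change sets against the
plant, not against a re-run of the detector. Everything derives from one
seeded RNG; identical configurations give byte-identical pages.

What the fixtures do **not** emulate: registry page chrome, layout
variants and historical redesigns, records with data points outside the
extraction table, non-English month names, malformed-but-parseable HTML
in the wild, server-side behaviour (rate limiting, redirects,
robots.txt). Passing the offline suite therefore demonstrates the
pipeline's correctness against the documented dialect contract, not
robustness to arbitrary live-site drift; the live transport is best
effort and the parsers target the classic page structure.

Corruption modes for failure-path testing: `TRUNCATE` (cuts the document
before any payload element → sentinel record), `DROP_TABLE` (removes the
status element → missing-status sentinel path), `BAD_DATE` (rewrites one
index date to unparseable text → index parse error → whole-trial
placeholder).

## Problem sizes and determinism

The test suite and the acceptance script use 100 simulated trials per
registry for the end-to-end round trip (≈ 350–400 versions each), 5%
corrupted pages for the resume check, 50 trials per registry for
outcome-edit recovery, 220 trials for the follow-up parameter-recovery
check, and a 93-trial cohort (57 mature/running, 10 stopped within five
years, 2 stopped after the five-year mark, 4 recent and stopped, 20
recent and running) for the follow-up-bias demonstration — sizes at which
every property is exact, not asymptotic. All randomness flows from
explicit seeds; hypothesis-based property tests run derandomized.

## Known limitations

* Live scraping targets the classic ClinicalTrials.gov history viewer
  and current DRKS URL shapes; registry redesigns can break it at any
  time. The parsers and the offline contract are the stable surface.
* Only the documented 16 + 13 data points are extracted; results
  sections, adverse events, secondary identifiers and site lists are out
  of scope.
* Outcome-change events are not classified by severity; byte-level
  sensitivity means cosmetic edits are reported alongside substantive
  switches, by design.
* The DRKS change-history page's native ordering is not relied upon;
  dates are sorted ascending defensively, which has not been validated
  against live pages here.
* `stopped_fraction` assumes a complete, Error-free history table;
  sentinel rows are not filtered before analysis.
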