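# trialhist

Structured extraction and analysis of **clinical trial registry entry
version histories** from ClinicalTrials.gov (classic history pages) and
DRKS.de (change-history pages).

## Why

A registry entry is not an immutable record: the responsible party can edit
it at any time, and registries archive every submitted version. Research
questions about trial conduct — did the recruitment period get quietly
extended? were the outcome measures switched after launch? how many trials
in a cohort were stopped, assessed fairly? — need the *history*, not just
the latest snapshot. Registries expose those histories only through web
pages meant for manual browsing. `trialhist` scrapes them into a tidy
long-format table (one registry-entry version per row) and implements the
analyses that motivate collecting them. It is written for meta-researchers,
systematic reviewers, and anyone auditing trial registration practice.

## What it does

**Acquisition.** For each trial id (`NCT########` or `DRKS########`) the
version index is fetched, then every archived version page. 16 data points
are extracted per ClinicalTrials.gov version (overall status, enrolment,
start date + precision, primary completion date + precision + type,
min/max age, sex, gender based, accepts healthy volunteers, inclusion
criteria, outcome measures, contacts, sponsors) and 13 per DRKS version.
Extraction is driven by a declarative table of CSS selectors plus regular
expressions; nested structures (criteria, outcome measures, contacts,
sponsors) are stored as canonical JSON inside single CSV cells. Dates given
only to the month are rounded to day 01 with a `month` flag in a sibling
precision column. Fetching is polite (configurable inter-request delay,
bounded retries, robots.txt) and failures never abort a bulk run: a failed
page becomes a row whose status is the reserved sentinel `Error`, and a
*resume* pass deletes exactly those rows and re-fetches them.

**Analysis.** Over a history table `H` with per-trial versions
`v_1 … v_k` at dates `t_1 ≤ … ≤ t_k`:

* *Recruitment-length change* — with launch dates taken from the earliest
  version with status `Recruiting` and both dates reported, and follow-up
  dates from the version active at `launch start + Δ` (default Δ = 1
  year), the change is `round(100 · L_fup / L_launch − 100)` percent,
  where `L = primary completion − study start` in days.
* *Outcome-change detection* — run-length scan of the encoded outcome
  structures: a new run opens at any byte-level difference between
  adjacent versions (even a single inserted space); the first version of
  each run is an event. Judging which events are substantive is left to
  human curation.
* *Follow-up-corrected status counts* — each trial's status is read from
  the version active at `t_1 + Δ` (default Δ = 5 years); trials first
  registered later than `today − Δ` are excluded; `stopped` means status
  in {Suspended, Terminated, Withdrawn}. This removes the variable
  follow-up-time bias of naive latest-status counts.

**Offline fixtures.** A seeded generator simulates trial histories (status
Markov chains, date/enrolment drift, material and single-whitespace
outcome edits) and renders them in both registry dialects, so the entire
pipeline is testable without touching a registry. Live-site layouts change;
the fixture templates are the dialect contract the parsers are tested
against.

## Worked example

Generate a 5-trial offline fixture cohort, download its histories, and run
the analyses:

```sh
$ ct-hist fixtures --registry ctgov --n-trials 5 --seed 42 --out-dir pages
wrote 14 version pages for 5 trials to pages

$ ct-hist dates NCT03356886 --fixture-dir pages
2008-07-03
2008-10-12

$ ct-hist download --registry ctgov --cohort SearchResults.csv \
      --out hv.csv --fixture-dir pages
14 rows written, 0 errors

$ ct-hist analyze recruitment --history hv.csv --out trial_dates.csv
5 trials analyzed
$ head -3 trial_dates.csv
nctid,recruitment_length_at_launch,recruitment_length_at_fup,recruitment_length_change
NCT03356886,1316,1427,8%
NCT14942603,884,1062,20%

$ ct-hist analyze followup --history hv.csv --out statuses.csv \
      --followup-years 5 --today 2022-01-05
stopped: 0/5 (0.0%)
```

Reading: trial NCT03356886 has two archived versions (2008-07-03 and
2008-10-12); its planned recruitment period was 1316 days in the version
where it first reported `Recruiting` and 1427 days in the version active
one year later — an 8% extension. None of the five trials had a stopped
status in the version active five years after first registration. The exit
code of `download`/`resume` is 0 exactly when no `Error` rows remain.

The same calls work against the live registries by omitting
`--fixture-dir` (best effort: registry sites redesign their history pages
from time to time; `--delay` defaults to 5 s between requests).

## Layout

```
src/trialhist/
  registry_model.py   # domain types, canonical JSON, history CSV schema
  ctgov_parser.py     # ClinicalTrials.gov extraction table + parsers
  drks_parser.py      # DRKS.de extraction table + parsers
  acquisition.py      # transports, polite fetching, download/resume
  analysis.py         # the three history analyses
  fixtures.py         # synthetic registry generator + HTML renderers
  cli.py              # the ct-hist command
docs/methods.md       # models, parameters, numerical choices, limitations
```
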