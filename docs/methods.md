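# Methods

## What the package computes

A clinical quality indicator (CQI) here is a computable artifact with four
declaration blocks:

* **metadata** — management attributes: name, version, authoring language
  plus a `|`-separated list of translation languages, free-text
  description, lifecycle status (`DRAFT`, `REVIEWING`, `PUBLISHED`,
  `DEPRECATED`), author, creation time, contact e-mail;
* **terminology bindings** — local codes (conventionally `TB0001`, …)
  bound to one or more terms, either from an external code system
  (ICD-10, SNOMED-CT, …) or from an archetype's internal `at`-code
  vocabulary.  A binding to several terms means *any of them*: the local
  code acts as a variable over the listed terms.  Inclusive ranges such
  as `at0014-at0022` expand to nine codes;
* **archetype bindings** — local aliases (`AB0001`, …) bound to an
  openEHR archetype, optionally placed in a template slot, with a map
  from local element codes (`E0001`, …) to openEHR element paths and an
  optional predicate list applied to every retrieve;
* **logic** — typed parameters (e.g. `MeasurementPeriod :
  Interval<DateTime>`) and ordered, acyclic `define` statements written
  in a CQL-style expression language.

For a **proportion (rate-based) measure**, reserved case-insensitive
define names map onto the standard populations:

    IP  = InitialPopulation
    D   = Denominator ∩ IP
    X   = DenominatorExclusions ∩ D,   E = DenominatorExceptions ∩ D
    D*  = D − X − E                         (effective denominator)
    N   = (Numerator ∩ D*) − NumeratorExclusions
    score = |N| / |D*|                      (exact rational; undefined if |D*| = 0)

Subtracting exclusions and exceptions identically is a deliberate
simplification: the two differ in clinical provenance (data-driven versus
clinician-attested), not in arithmetic.  A **count measure** is declared
by a `MeasureObservation` define; a boolean observation counts the
patient, a numeric one contributes its value, and the measure result is
the per-patient map plus its total.

## The expression language

The logic sub-language is a deliberately small CQL subset: retrieves
`[ALIAS : TERM]` (TERM optional — a terminology local code or an inline
`ICD10::[I10]` shorthand), `where` filters whose bare element codes refer
to the current entry, `exists` / `Count` / `First` / `Last (… sort by …)`,
`Interval[a, b)` literals with bracket-controlled bound inclusivity,
`during`, three-valued `and`/`or`/`not`, comparisons, arithmetic,
`AgeInYearsAt`, calendar shifts (`+ 6 months`, `- 24 hours`) and
`start of` / `end of`.  Double-quoted strings name things (define
references), single-quoted strings are text literals; `//` comments;
keywords are lowercase and case-sensitive.  Out of scope by design:
multi-source `with … such that` joins, libraries/includes, user function
definitions, and the QDM/QUICK data models — archetype binding replaces
the data-model layer entirely.

Semantics follow CQL's null logic: a comparison with null is null, a null
`where` condition drops the row, `exists` of the empty list is `false`,
`Count` of it is `0`, and division by zero is null.  Where a scalar is
required, a singleton list coerces to its element, the empty list to
null, and a longer list is a type error.  A retrieve's term constraint
keeps an entry when **any** of its coded element values belongs to the
value set; this is exact, extensional membership — canonical system name
plus case-sensitive code, no prefix matching, no subsumption, no
terminology server.  Both shipped indicators have exactly one coded
element per bound archetype, so "any coded element" is unambiguous there.

## Worked decisions in the blood-pressure indicator

The controlling-high-blood-pressure measure (patients 18–85 with
essential hypertension whose blood pressure is controlled below 140/90
mmHg) needs several boundary decisions that its prose statement leaves
open.  The package fixes them as follows and the synthetic generator
plants a patient on each side of every boundary:

* **Age 18–85**: completed years at the *start* of the measurement
  period, both bounds inclusive.  Anchoring at period start is the
  reproducible choice; "age during the period" would make membership
  time-dependent.
* **Diagnosis "within the first six months or any time prior"**: onset
  date ≤ period start shifted by six *calendar* months (day-of-month
  clamped, e.g. 31 August + 6 months = 28/29 February), boundary
  inclusive.
* **"Most recent visit"**: the blood-pressure entry with maximal entry
  time inside the half-open period `[start, end)`; ties broken by load
  order.  Both systolic < 140 and diastolic < 90 must hold on that one
  entry.
* **No blood pressure in the period**: the patient stays in the
  denominator and fails the numerator — the measure lists no such
  exclusion.
* **Exclusion timing**: renal disease (chronic kidney disease `N185`,
  end-stage renal disease `N18.6`) counts when recorded strictly before
  the period end ("before or during"); pregnancy (`Z32.100`) only when
  recorded inside the period.
* **Deprecated artifacts** still evaluate; validation downgrades the
  status to a warning so historical reports can be reproduced.

The APACHE-II example ("patients whose APACHE II score is not less than
15 within 24 h after entering the ICU") reads *within 24 h* inclusively:
the qualifying window is the closed interval `[admit, admit + 24 h]`, and
a score of exactly 15 at exactly +24 h counts.

## Parsing and serialization

The language keywords come straight from the binding tables
(`archetype`/`name`/`in template`/`with path`/`elements`/`with
predicates`; `term`/`uri`/`bind`/`code`/`archetype`; the nine metadata
keys); the concrete grammar around them is this package's own
reconstruction.  The parser is a hand-written lexer plus recursive-descent
parser — small enough that a parser generator would add a dependency
without removing complexity — with a raw-scan mode for code lists, whose
tokens (`N18.6`, `at0014-at0022`) do not follow identifier rules.  Every
syntax error carries a 1-based line/column span and an expected-token
hint.  Date-time literals accept both `@2016-01-01T00:00:00` and the
quoted space-separated form `@"2016-01-01 00:00:00"`.

`serialize_text` emits canonical formatting and is a two-sided inverse of
the parser on valid artifacts; the XML serializer maps declaration blocks
to structured elements and carries expression logic as canonical text
inside `predicate`/`default`/`define` elements (structured expression XML
would double the surface for no added fidelity), validated against the
shipped `cqi-1.0.xsd`.  Both round trips are property-tested against a
seeded generator of random valid artifacts.

## Repository model

Each (archetype, template) pair an indicator retrieves becomes one flat
table: columns `patient_id`, `entry_time`, plus the bound element paths.
This is a deliberate stand-in for a full archetype-relational mapping —
enough structure to address values by path, storage-agnostic behind the
`retrieve` contract (an SQLite or server backend could replace the
in-memory tables without touching the engine).  CSV cells are typed by
lexical shape: `system|code` coded values, `value|unit` quantities,
ISO-8601 timestamps (timezone-naive, second precision), bare numbers,
`true`/`false`, free text; the empty cell is null.  Intervals default to
closed-open; explicit brackets override.  Demographics are ordinary
entries of the person/birth-data archetypes, not a special table.  All
expression computation happens locally after retrieval; the repository
only answers path-addressed fetches with optional coded-value and
time-window filters.

## Synthetic cohorts and what they do (not) show

The generator emulates exactly the data the two indicators consume:
coded diagnoses with onset dates, timestamped systolic/diastolic
pressures, one birth date and person record per patient, typed
admissions, timestamped imaging results and APACHE-II scores.  Defaults
(200 patients; ages uniform 16–95 so both age boundaries have mass; 60 %
hypertension prevalence, 55 % controlled among hypertensives, 10 % late
diagnoses; exclusion probabilities 4 %/2 %/1 %/6 %; 0–5 visits; controlled
pressures ≈ N(124, 8)/N(76, 6) clipped below 140/90, uncontrolled
systolic ≈ N(152, 10) clipped to ≥ 140; calendar-year-2016 period) are
chosen to keep every population non-trivially occupied at n = 200, not to
mimic any real registry.  A single seeded `random.Random` stream drives
each cohort: same spec and seed means byte-identical files.

Eleven boundary patients are planted at the head of every cohort (ages
17/18/85/86, diagnosis exactly at and one day past the six-month mark, a
blood pressure at the last in-period second and a decoy exactly at the
period end, a renal and a pregnancy exclusion, a zero-visit patient), so
every documented boundary decision is exercised on every run.  The
ground-truth ledger records intended flags *by construction* while the
rows are written, never by running the engine.

Passing tests therefore show that the engine, an independent brute-force
interpreter over the raw CSV rows, and the generator's bookkeeping agree
exactly on well-formed data with planted truth.  They do not show
robustness to real-EHR phenomena the generator deliberately omits:
longitudinal disease progression, missing and contradictory records,
free-text diagnoses, timezone or precision artifacts, or realistic
clinical value distributions.

## Numerical and procedural choices

Scores are exact `fractions.Fraction` values; floats appear only in
report output.  Quantities compare by magnitude against bare numbers and
require matching units against other quantities.  `Last`/`First` drop
entries whose sort key is null.  Evaluation order is a stable topological
sort of the define dependency graph (declaration order among independent
defines); cycles are rejected at validation.  Results are independent of
row order except where the documented tie-break uses load order.
Reports omit the evaluation timestamp unless requested (`--stamp`) so
that repeated runs are byte-identical.  CLI exit codes separate syntax or
validity errors (1), I/O failures (2), repository/schema mismatches (3)
and parameter errors (4).

Problem sizes used by the test suite and the acceptance script — 100/25
cohorts of 200 patients, 30 ground-truth seeds, 500/200 round-trip
artifacts, 20/10 ICU cohorts of 100 — are the package's verification
conditions; they complete in well under a minute on one CPU.

## Known limitations

One indicator per artifact (no libraries or cross-artifact reuse); no
continuous-variable, ratio, stratified or risk-adjusted measures; no
terminology hierarchy; no real openEHR REST/AQL connectivity; the
visual-editor and dashboard-GUI layers of a production deployment are out
of scope — the dashboard command emits machine-readable summaries only.
ICD-10 codes are not checked against an official release: clinical
sources mix dialects (`N185` alongside `N18.6`), and both are kept
verbatim as distinct opaque codes.
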