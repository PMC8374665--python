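# Methods

This note records how `ichomdq` defines, scores and synthesises the data it
assesses: the conventions behind each quality dimension, what the synthetic
cohort does and does not emulate, and the numerical choices made where the
design was genuinely open.

## The assessed table

All checks consume a flat, visit-centered table: one row per hospital visit
record, 22 columns — 21 ICHOM heart-failure items (identifiers,
demographics, baseline health status, treatments, burden of care,
mortality) plus a visit identifier.  Raw values are kept verbatim as text;
parsing produces, per cell, exactly one of three statuses (`ok`, `missing`,
`type_failure`) plus a typed value.  Conventions:

- **Missingness is the empty field, and nothing else.**  The ICHOM unknown
  response 999 parses as a legal value (`ok`, flagged unknown) for every
  variable that declares it, including the date of death.
- **Zero-coded measurements parse fine.**  A height or weight of 0 is an
  extraction artifact standing for a missing measurement; it is
  deliberately treated as a *range* violation, not a type failure and not
  missingness, because that is how it manifests in the assessed format.
- Dates are accepted in the ICHOM DD/MM/YYYY dialect and in ISO 8601;
  internal typed values are ISO.  Calendar-invalid dates (31/02) are type
  failures.
- Count variables (hospital admissions/appointments in the last 12 months)
  accept any integer or 999; negative integers are range violations rather
  than type failures.

Row order never matters: every check is invariant under permutation of
rows (ordering needed by the temporal checks is established internally
from patient ID, arrival date and visit ID, with the stable tie-break on
the visit ID).

## Scoring conventions

Every check reports `numerator / denominator` and a score in percent,
`100·(1 − numerator/denominator)`, rounded half-up to two decimals (raw
integers are retained, so full precision is always recoverable).

- **Uniqueness** counts *records*, not groups: in a colliding group every
  member counts, and the denominator is all records.  Records sharing a
  visit ID while agreeing on every field are *exact* duplicates — reported
  separately and excluded from result 1, which requires differing inputs.
- **Type, range and completeness** are scored per variable and combined by
  unweighted mean over the 22 variables (not pooled over fields): whether
  the reference methodology pooled or averaged is not documented, and the
  mean-over-variables convention reproduces its published arithmetic.  A
  variable with no assessable field scores 100 with an explicit vacuous
  flag, avoiding 0/0.
- **Rules** are declarative field comparisons (default: arrival ≤
  discharge, discharge ≤ death).  A rule counts only where every referenced
  field is well-typed; the denominator is records with at least one
  evaluable rule.
- **Completeness** treats 999 as complete and reports per-variable unknown
  rates separately.  The date of death carries the only
  valid-incompleteness rule: it is scored on the records where the field
  should exist — deaths during the visit, identified from the data as a
  death date inside the [arrival, discharge] interval — and the
  unconditional rate is reported alongside.  With a hospital EHR as the
  only source, a missing death date is indistinguishable from an
  out-of-hospital death, which is exactly why the incompleteness is valid.
- **Dimension scores** are unweighted means of their components
  (uniqueness: 2, consistency: 3, correctness: 1 + one per condition).
  Stability contributes monthly series, never a scalar; and the report has
  deliberately no single composite number.
- **Correctness aggregation** is a package convention (mean over component
  checks).  The reference assessment prints a correctness total that does
  not equal any simple combination of its component rates; the component
  scores are therefore always retained so any weighting can be applied.

## Temporal stability

For each 0/1/999 indicator, records are binned by calendar month of the
arrival date; the numerator counts 1s and the denominator all records of
the month (0 and 999 included; records with unparseable arrivals are
excluded and reported).  Months with fewer than 10 records (configurable)
are flagged low-support; empty months inside the observed span appear with
*undefined* — not zero — frequency.

`detect_shift` is a convenience extension beyond the qualitative
assessment and is off by default in reports.  For each candidate month it
compares the mean frequency over the supported months of the trailing and
leading 12-month windows and returns the month with the largest absolute
gap, provided the gap exceeds 50% of the before-mean and each window
contributes at least 3 supported months.  These defaults localise a 0.3×
step to within one month at monthly supports of a few dozen records; they
are not tuned for gradual drift, which the relative-change threshold
deliberately ignores.

## The synthetic cohort

The generator emulates the assessment's study conditions: a 2006-01-01 to
2017-11-07 visit stream for a congestive-heart-failure cohort with ICHOM
0/1/999 coding and DD/MM/YYYY dates.  Defaults, with rationale:

- **Scale**: 1,000 patients, geometric visit counts with mean 10 — a
  desk-scale rendering (~8,000 records) of a cohort whose full size was
  12,503 patients and 142,345 visit records (~11 visits/patient).  The
  acceptance tests scale the same generator to 100,000 rows.
- **Demographics** (unpublished in the reference): age 40–95 at first
  visit, 55% male, heights ~N(168, 9) cm, per-patient BMI ~N(28, 5)
  clipped to [16, 48] so that clean rows can never trip the BMI or
  inversion checks.
- **Visits**: 55% same-day appointments, otherwise admissions with
  geometric length-of-stay (mean 4 days); per-visit in-hospital death
  probability 0.02, truncating the patient's stream; the death date is
  written only on the death visit.  Each patient's visits fall on distinct
  days — in the flat path, same-day duplication exists only where planted,
  so planted counts are exactly recoverable.  Same-day multi-department
  visits live in the relational source, where they are the generative
  mechanism for date-matching duplication.
- **Conditions**: lifetime prevalences 0.60 (hypertension), 0.40
  (diabetes), 0.35 (atrial fibrillation, prior MI) with onset at a uniform
  visit; flags follow ever-diagnosed semantics.
- **Documentation phenomena**: from 2011-01-01 the probability that an
  established history is actually recorded at a visit is multiplied by 0.3
  (the regime shift observed as drastically reduced recording of past
  conditions), and medication recording follows gentle monthly uptrends
  (strongest for beta blockers and diuretics).  These are generation-time
  practice phenomena, not ledger errors; they produce "natural"
  temporal-order violations exactly as the real extraction did.  The
  first half of 2016 is volume-thinned (factor 0.1) to reproduce months
  with fewer than 10 records.
- **Error plan** (defaults mirror the observed burden): visit-ID
  collisions 1.2%, same-day clones 2.8%, zero-coded height/weight 85%,
  54 out-of-range heights, 20 out-of-range weights, 16 early arrival
  dates, 16 low-BMI and 180 high-BMI records, history-flip rates
  6.33%/12.11%/6.12%/12.11% for AF/HT/DM/MI.

Planting is strictly in place, so the row count — and with it every
denominator — never changes: collisions reassign one member's visit ID
within a sampled pair; clones overwrite one member with the other's data
(keeping its own visit ID); flips rewrite a later recorded "1" to "0"
where an earlier "1" survives, so each flip yields exactly one
temporal-order violation.  Flip rates are resolved against the *flippable*
rows (non-first recorded 1s); early-arrival planting is restricted to
rows without recorded history, because moving a flag-1 row to the front of
a patient's timeline would fabricate order violations.  Planted
out-of-range and implausible-BMI rows are constructed not to contaminate
each other's counts (out-of-range heights get weights keeping BMI
plausible, low-BMI rows keep height and weight individually in range).
Classes touching the same columns use disjoint rows; flips may share rows
with height/weight classes (disjoint columns), which the ledger flags.

Two planting modes: `exact_count` (fractions rounded to exact counts;
bit-exact recovery) and `rate` (binomially realised).  Determinism: every
stage draws from its own named substream spawned in a fixed order, and
each class always consumes a fixed-size priority vector, so identical
(config, seed) gives byte-identical output and disabling one class leaves
the others' selections untouched.

**What the synthetic data does not emulate** — and hence what passing
tests do not show about real data: free-text content, realistic ICD-9/ATC
code mixtures beyond the stub lists, inter-variable clinical correlation
(comorbidity clustering, medication–condition coupling), secular mortality
trends, or the reference database's 37% unconditional death-date rate,
which is not reproducible under death-visit-only recording and is left as
reported output rather than a target.

## The mapper

`map_to_ichom` reproduces the assessed extraction procedure rather than an
idealised one: a left-outer-join spine of (patient, visit), diagnoses
joined by visit ID, drugs and measures joined by (patient ID, arrival
date).  Consequences, all deliberate: two same-day visits receive the same
clinical data; several same-date measurements multiply a visit into
partially duplicated rows; absent measurements are zero-coded; and a
history flag is 1 if any diagnosis up to and including the visit date
matches the condition's code list, else **0 — never 999** — modelling the
inability to distinguish "confirmed absent" from "not recorded" (an
optional strict mode emits 999 instead, for contrast experiments).
Burden-of-care counts are the patient's visits in the 365 days strictly
before arrival (admissions: discharge ≠ arrival; appointments: same-day);
the reference computation is undocumented, so this is an assumption.
Comorbidity, habit and medication code lists are configurable stubs
(ICD-9/ATC prefixes) because the reference appendices are unpublished; the
heart-failure cohort list (19 ICD-9 428.x codes) ships built in.

## Numerical choices and degenerate inputs

- Plausibility ranges: height 100–250 cm, weight 20–350 kg (assumptions;
  the reference prints none); BMI bounds 10/70 kg/m² with strict
  inequalities; date-window range checking applies to the arrival date
  only, matching the error classes actually reported.
- Rounding is half-up at two decimals everywhere a score is printed;
  trailing zeros are dropped in text output (98.00% prints as 98%).
- Parsing never raises on cell content; schema problems (missing or
  unexpected columns) raise naming the column, with a lax mode that drops
  extras with a warning.
- Empty cohorts, all-missing columns and zero-denominator months are
  handled explicitly (warning flags, vacuous scores, undefined
  frequencies) rather than silently.

## Known limitations

- The temporal-order check assumes visit ordering by arrival date is
  meaningful; records with unparseable arrivals are excluded from the scan
  but kept in denominators.
- `detect_shift` finds a single dominant step; multiple shifts or
  drift-plus-step patterns are out of scope, as are the
  information-geometric temporal-variability metrics of the broader
  methodology.
- Uniqueness is exact comparison only — no fuzzy or phonetic record
  linkage.
- The package assesses the 22-variable pilot subset, not the full 72-item
  ICHOM heart-failure set, and produces single-site reports only.
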