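# ichomdq

Data-quality assessment of ICHOM heart-failure visit records.

Hospitals increasingly need to show the health outcomes they achieve, and
the only scalable source of outcomes evidence is the routine electronic
health record (EHR).  Whether EHR extracts are *good enough* for outcomes
measurement is an empirical question: `ichomdq` answers it for the
heart-failure subset of the ICHOM (International Consortium for Health
Outcomes Measurement) standard set, assessing a flat, visit-centered table
of 22 variables (21 ICHOM items plus a visit identifier) along five quality
dimensions:

- **Uniqueness** — partially duplicated visit records.  Result 1 counts
  records whose visit identifier is shared by a record with *different*
  field values (the artifact of merging two same-visit measurements);
  result 2 counts records with a same-day, clinically identical twin under
  a *different* visit identifier (the artifact of date-matching joins).
  Both are percentages of all records, `100·(1 − violating/total)`.
- **Consistency** — compliance by *type* (does each field parse as its
  declared kind), by *range* (plausibility intervals, response-code
  domains, extraction-window dates) and by *multivariate rules* (arrival ≤
  discharge; discharge ≤ death).  Type and range are scored per variable
  and averaged; the dimension score is the unweighted mean of the three.
- **Completeness** — proportion of non-empty fields per variable, with
  *valid incompleteness* handling: the date of death exists only when the
  patient died during the visit, so it is scored on that subset and its raw
  unconditional rate is reported separately.  The unknown response (999) is
  a recorded value, not missingness.
- **Temporal stability** — monthly relative frequencies of each binary
  indicator (share of that month's visit records carrying a 1), flagged
  when a month has fewer than 10 records; assessed qualitatively, with an
  optional change-point detector for abrupt documentation shifts.
- **Correctness** — body-mass index `BMI = weight / (height/100)²` flagged
  below 10 or above 70 kg/m²; height/weight value-inversion candidates
  (weight in kg exceeding height in cm); and the temporal order of history
  flags — once a record says a patient has a history of atrial
  fibrillation, hypertension, diabetes or myocardial infarction, no later
  record may say they do not.

Because the hospital data such assessments run on are private, the package
ships a seeded **synthetic relational-EHR generator** (patients, visits,
diagnoses, drugs, measures) and the **visit-centered ETL mapper** whose
left-outer-join, date-matching merge faithfully reproduces the real
extraction artifacts: join-induced row duplication, zero-coded missing
height/weight, and "no history" flags that actually mean "not recorded".
Every error class can be planted at an exact count or a rate, with a
ground-truth ledger for recovery testing.

## Worked example

```sh
ichomdq generate --seed 7 --out cohort
ichomdq assess cohort/visits_flat.csv --out assessment
```

generates a synthetic cohort of 1,000 heart-failure patients (7,999 visit
records, 2006–2017) with the default error burden planted, assesses it, and
prints:

```
   uniqueness: 98%
               - uniqueness_1: 98.8% (96/7999)
               - uniqueness_2: 97.2% (224/7999)
  consistency: 97.41%
               - consistency_type: 100% (0/168160)
               - consistency_range: 92.23% (13672/168160)
               - consistency_rules: 100% (0/7999)
 completeness: 100%
               - completeness: 100% (0/168160)
  correctness: 92.38%
               - bmi_plausibility: 97.55% (196/7999)
               - history_order[Atrial fibrillation]: 92.95% (564/7999)
               - history_order[Hypertension]: 86.5% (1080/7999)
               - history_order[Diabetes mellitus]: 92.15% (628/7999)
               - history_order[Prior myocardial infarction]: 92.76% (579/7999)
    stability: 8 monthly series (qualitative)
```

Reading the output: 1.2% of records collide on a visit identifier and 2.8%
have a same-day clone (uniqueness 98.8% and 97.2%, dimension mean 98%);
every value parses as its declared type and no date rule is broken, but
range compliance is pulled down by the zero-coded heights and weights, the
planted out-of-range measurements and 16 pre-window arrival dates; all
fields are complete once the death date's valid incompleteness is handled;
correctness flags exactly the 196 planted implausible BMIs (16 low + 180
high) plus the history flags whose recording collapsed after the planted
2011 documentation shift.  `assessment/report.json` holds the full
machine-readable report and `assessment/findings.csv` the record-level
findings.  The same numbers are reproducible from the library:

```python
from ichomdq import GeneratorConfig, generate_flat, plant_errors, run_assessment

cfg = GeneratorConfig(seed=7)
table, ledger = plant_errors(generate_flat(cfg), cfg)
report = run_assessment(table)
print(report.summary())
```

A relational workflow (`ichomdq generate --relational`, `ichomdq map`)
exercises the cohort selection (ICD-9 428.x) and the ETL mapper instead of
planting errors into the flat table directly.

## Layout

| module | contents |
| --- | --- |
| `ichomdq.dictionary` | the 22-variable ICHOM heart-failure schema, value parsing, code lists |
| `ichomdq.table` / `ichomdq.io` | the visit-table container and CSV round-trip I/O |
| `ichomdq.synthetic` | seeded cohort generator, error planting, ground-truth ledger |
| `ichomdq.mapper` | cohort selection and the relational→flat visit-centered mapping |
| `ichomdq.structural` | uniqueness, consistency and completeness checks |
| `ichomdq.semantic` | stability series, change-point detection, correctness checks |
| `ichomdq.report` / `ichomdq.cli` | dimension aggregation, JSON/CSV reports, command line |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
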