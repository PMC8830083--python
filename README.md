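# cqi — configurable clinical quality indicators

Hospitals measure care quality through *clinical quality indicators*:
standardized, computable statements such as "percentage of patients 18–85
years of age with a diagnosis of essential hypertension whose blood
pressure was adequately controlled (< 140/90 mmHg) during the measurement
period".  Encoding such indicators directly against a data warehouse ties
them to one institution's schema and buries the clinical intent in SQL.
This package implements the alternative: indicators written in a small
CQL-style expression language whose clinical content is supplied by
**openEHR archetype bindings** (local aliases over archetype element
paths) and **terminology bindings** (local codes over ICD-10 / SNOMED-CT
terms or archetype-internal `at`-codes, with one-to-many "any of"
semantics), plus management metadata for sharing and lifecycle.

It is aimed at clinical informaticians and quality-measurement teams who
want indicator definitions that are portable across openEHR-based
repositories and auditable down to per-patient intermediate values.

The package provides:

* a typed object model with full cross-reference validation;
* a parser and canonical **text** (`.cqi`) and **XML** serializers that
  round-trip artifacts identically;
* an **evaluation engine** computing eCQM-style proportion measures

  `score = |numerator| / |denominator − exclusions − exceptions|`

  (exact rational arithmetic, CQL three-valued null logic) and count
  measures, over a flat archetype-mapped repository loaded from CSV;
* a deterministic **synthetic-cohort generator** that plants known
  population membership (including boundary patients) and writes a
  ground-truth ledger for verification;
* a CLI (`cqi parse|validate|evaluate|simulate|dashboard`) and
  machine-readable measure reports.

Two worked indicators ship as fixtures: the controlling-high-blood-
pressure proportion measure above, and an ICU count measure ("patients
whose APACHE II score is not less than 15 within 24 h after entering the
ICU").  See `docs/methods.md` for the semantics and every documented
boundary decision.

## Worked example

Generate a 200-patient synthetic cohort and evaluate the shipped
blood-pressure indicator over it:

```sh
cqi simulate --out-dir cohort --n 200 --seed 7
cqi evaluate src/cqi/fixtures/controlling_high_blood_pressure.cqi \
    --data-dir cohort
```

The report (JSON on stdout) contains:

```json
{
  "counts": {
    "initial_population": 95,
    "denominator": 95,
    "denominator_exclusions": 11,
    "effective_denominator": 84,
    "numerator": 36
  },
  "score": 0.42857142857142855,
  "score_exact": "3/7"
}
```

Of the 200 synthetic patients, 95 are 18–85 years old with a
hypertension diagnosis no later than six months into 2016 (the initial
population, which this measure's denominator equals); 11 are excluded
for renal disease before the period end or pregnancy during it; of the
84 remaining, 36 had systolic < 140 **and** diastolic < 90 mmHg at their
most recent in-period visit, giving a control rate of 36/84 = 3/7 ≈
42.9 %.  These counts equal the generator's `cohort/ledger.json` exactly
— that agreement is what the test suite asserts across many seeds.

Per-patient auditing, e.g. why a patient is excluded:

```python
>>> from cqi import load_fixture_indicator, BP_FIXTURE, schema_from_indicator, load_fixture
>>> from cqi.engine import evaluate_for_patient
>>> ind = load_fixture_indicator(BP_FIXTURE)
>>> repo = load_fixture("cohort", schema_from_indicator(ind))
>>> evaluate_for_patient(ind, repo, "P00009").flags
{'initialpopulation': True, 'denominator': True,
 'denominatorexclusions': True, 'numerator': True}
```

(P00009 is a planted boundary patient: controlled blood pressure but
end-stage renal disease before the period, so the exclusion removes them
from the effective denominator.)

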