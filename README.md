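# emrforge

**emrforge** is a pipeline for turning raw administrative EMR (electronic
medical record) extracts into analysis-ready research cohorts, with the
derived proxy measures and statistical validity checks that health-services
research needs.

It addresses a common situation: a hospital's EMR stores data as five
record-level tables (demographic, movement, billing, pharmacy, diagnosis),
switched diagnosis nosologies mid-period (ICD-9-CM before a cut-over date,
ICD-10-AM after), and contains no direct measures of disease complexity or
socioeconomic status. The package provides, as importable modules and as a
CLI:

* **codemap** — backward mapping of ICD-10-AM codes onto ICD-9-CM through a
  crosswalk, with a *code-modification* fallback for codes the crosswalk
  misses: zero addition (append up to two trailing `0`s), then truncation
  (drop trailing characters down to the 3-character heading); the first
  crosswalk hit wins and the route is recorded. The same engine collapses
  the standardized ICD-9-CM pool onto mutually exclusive CCS-style disease
  categories. Per-role (primary/secondary diagnosis) mapping statistics and
  physician-audit validity arithmetic are built in.
* **cohort** — the record → visit → patient aggregation cascade: per-visit
  sums/flags full-outer-joined across tables, inflation adjustment of
  charges to a base year, visit-level exclusions (study window, minimum
  age) and patient-level exclusions (no primary diagnosis, sentinel birth
  year 1900, sex-incompatible diagnoses), each logged in a chain-consistent
  exclusion audit.
* **measures** — per-patient proxies: the Charlson Comorbidity Index
  (CCI; Deyo ICD-9-CM prefix adaptation, weights 1/2/3/6 with hierarchy
  pairs), the Polypharmacy Score (PPS; distinct prescription drugs per
  visit, patient-level maximum), housing type resolved from postal codes
  (public-housing flat-type lookup with majority rule, private-housing
  list, non-residential → missing), subsidy status, and RSR — the percent
  of cumulative hospital charges paid by government subsidy.
* **validate** — Spearman correlations with Holm step-down adjusted
  confidence intervals, log-linked negative binomial models of utilization
  counts, multinomial-logistic and linear models of subsidy status and RSR
  against housing group, Pearson chi-square and Kruskal–Wallis tests.
* **synthgen** — a seeded generator of the full five-table substrate with a
  ground-truth ledger (planted conversion routes, rule violators, latent
  complexity tiers, housing-dependent subsidy behaviour), so every stage is
  testable end to end without access to any real EMR.

## Worked example

Convert single codes through a crosswalk with the modification fallback:

```python
from emrforge import convert_code, mapping_rate
from emrforge.synthgen import make_fixture_crosswalks

icd10_to_icd9, icd9_to_ccs = make_fixture_crosswalks()
for code in ("A09", "N39", "K3580", "Z999"):
    c = convert_code(code, icd10_to_icd9)
    print(f"{code:7s} -> {str(c.target):6s} method={c.method}")
print("mapping_rate(810459, 930248) =", mapping_rate(810459, 930248))
```

```
A09     -> 0091   method=direct
N39     -> 5990   method=zero_added_1
K3580   -> 5409   method=truncated(2)
Z999    -> None   method=unmapped
mapping_rate(810459, 930248) = 87.1
```

`A09` is a direct crosswalk hit; `N39` only maps after one appended zero
(`N390` is the key); `K3580` only maps after dropping two trailing
characters to the heading `K35`; `Z999` matches no candidate and is flagged
for exclusion. `mapping_rate` is the percentage of codes mapped, at the
one-decimal reporting precision.

Run the whole pipeline on a synthetic cohort:

```bash
emrforge run-all --n-patients 500 --seed 7 --no-validation --out demo/
# pipeline complete: 4474 visits, 474 patients → demo/
```

The manifest written to `demo/manifest.json` chains every stage count:

```
"visits_built": 4494  →  "visits_kept": 4474
  inpatient_outside_study_window removed  8
  age_below_minimum_at_visit     removed 12
"patients_built": 500 →  "patients_kept": 474
  no_primary_diagnosis           removed 10
  birth_year_1900_or_earlier     removed  7
  sex_incompatible_diagnosis     removed  9
```

Those removal counts equal the generator's planted rule violators exactly —
the property the cohort stage is tested against. `demo/` also contains
`visits.csv`, `patients.csv` (with CCI/PPS/housing/subsidy measures),
`mapping_stats.json`, `exclusion_log.json` and `profile.json`.

Each stage is also runnable standalone (`emrforge synth`, `standardize`,
`phenotype`, `build-cohort`, `measures`, `validate`); see `--help`.

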