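# Methods

This note documents the models, algorithmic choices, defaults, and known
limitations of emrforge, in the order the pipeline runs.

## Code standardization and phenotyping

**Problem.** The EMR coded diagnoses in ICD-9-CM before a cut-over date and
in ICD-10-AM afterwards. Longitudinal analysis needs one coding frame, so
the newer codes are mapped *backward* onto ICD-9-CM (ICD-10 is finer than
ICD-9, so backward mapping loses less information than forcing old codes
forward). The standardized pool is then collapsed onto a few hundred
mutually exclusive disease categories (CCS-style) to trade granularity for
sparsity.

**Fallback algorithm.** For a code missing from the crosswalk, candidates
are tried in a fixed priority order until one is a crosswalk key:

1. the exact normalized code (upper case, periods stripped);
2. zero addition: `code+"0"`, then `code+"00"`;
3. truncation: one trailing character at a time, re-testing the crosswalk
   at every intermediate length, down to a minimum of 3 characters (the
   ICD heading; the V/E/letter prefix counts toward the 3).

Design choices worth stating explicitly:

* *Precedence.* Zero addition is tried before truncation because it
  preserves all of the source code's specificity, whereas truncation
  discards detail. The precedence is a switch (`prefer_truncation`) so the
  alternative ordering can be tested; both orders are deterministic.
* *Truncation granularity.* "Down to the 3-character heading" is
  implemented as one character per step with a crosswalk probe at each
  length, not a single jump to length 3 — a 4-character key must be able
  to catch a 5-character code.
* *One-to-many rows.* Backward maps may list several targets for one key.
  The stored file order is kept, the first target is returned, and an
  ambiguity flag is set and tallied. This keeps conversion deterministic
  and auditable rather than silently choosing.
* *Era rule.* Whether a raw code is already ICD-9-CM is decided by a
  per-record nosology column when present, otherwise by comparing the
  visit date against the configurable cut-over date (default 2010-01-01).
* *Unmapped codes* are flagged and excluded downstream but retained in the
  output with their `unmapped` method, so exclusions stay attributable.

Mapping statistics are tallied per diagnosis role (primary = the
hospital's main diagnosis for the visit; secondary otherwise), on both
code instances and unique codes, with the conservation invariant
`direct + zero_added + truncated + unmapped = total` enforced at
construction. Percentages are derived on both the total and the mapped
denominator, because published audit tables use both. The physician-audit
arithmetic (`validity_summary`) reports the valid fraction of a rated
sample of modified codes and the sampling fraction relative to all
modified unique codes; rates are reported at one-decimal precision.

## Cohort construction

Records aggregate to visits (sums for amounts, OR for flags,
count-distinct for drugs), the per-table aggregates full-outer-join on
visit id — a visit seen in *any* of movement/billing/pharmacy exists
exactly once — and demographics attach by patient id. Charges are
inflation-adjusted per bill (`amount × index(year)`, base year 2015,
multiplier 1 at base) *before* patient-level summation, so patient totals
are in constant dollars.

Exclusion rules run in a fixed order, each appending a row to an
`ExclusionLog` whose before/after counts must chain exactly:

1. (visit) data quality: unresolvable visit or birth dates;
2. (visit) inpatient stays not fully inside the study window
   (2005-01-01 … 2013-12-31 by default) — the rule deliberately targets
   inpatient visits only;
3. (visit) patient younger than 21 completed years at the visit date;
4. (patient) no primary diagnosis on record;
5. (patient) birth year ≤ 1900 (the EMR's default-birth-year sentinel);
6. (patient) sex-incompatible diagnoses, from an editable
   `sex,prefix` rule file (defaults: pregnancy/childbirth and
   female-infertility ICD-9 ranges for males; prostate-range codes for
   females). Patients with missing sex whose codes would trigger a
   sex-specific rule go to a data-quality rule instead of being silently
   kept.

Conventions the data do not dictate, chosen once: age is completed years
(floor); the observed period is the span from first to last included
visit plus one day, in years; primary-diagnosis presence is evaluated on
diagnoses that survived standardization (a code that fails *phenotyping*
still counts — it is a valid ICD-9-CM code); re-running any exclusion on
already-filtered data removes zero rows (idempotence, tested).

## Derived measures

* **CCI** — 17 Deyo comorbidity categories defined by ICD-9-CM code
  prefixes, shipped as an editable `category,prefixes,weight,supersedes`
  file with the original 1/2/3/6 weights. Hierarchy pairs (diabetes with
  complications over diabetes; moderate/severe over mild liver disease;
  metastatic solid tumour over any malignancy) keep only the severe
  member. All of a patient's included primary and secondary codes
  contribute; no per-visit CCI is produced.
* **PPS** — distinct prescription drug codes per visit, excluding
  non-prescription items and devices; the patient score is the maximum
  over visits (0 for none). Distinctness is by drug code only.
* **Housing type** — the patient's latest postal code against a
  public-housing block lookup (`postal,flat_type,proportion`) and a
  private-housing postal list. Mixed blocks take the majority flat type;
  exact ties break toward the larger flat type (deterministic). Postals
  on neither list are non-residential → missing. Flat types group into
  rental/studio/1–2-room, 3-room, 4-room, 5-room/executive, private.
* **Subsidy status** — subsidized if every visit carried the subsidy
  flag, nonsubsidized if none did, else mixed. **RSR** = 100 × total
  subsidy / total charges (both inflation-adjusted, so the ratio is
  unaffected within a year); undefined (missing) at zero charges.

## Validation harness

* Spearman correlations (average ranks for ties) with Fisher-z confidence
  intervals. "Holm-adjusted CIs" is interpreted as step-down alpha
  allocation: with the m pairs ordered by p-value, the k-th smallest is
  built at confidence level 1 − α/(m−k+1), never narrower than the
  unadjusted interval; unadjusted intervals are also emitted. Missing
  values are removed pairwise; a constant vector yields a per-pair error
  result without aborting the other pairs.
* Utilization counts: log-linked negative binomial (NB2) with dispersion
  estimated by maximum likelihood; on non-convergence the model falls
  back to Poisson and says so in the result rather than failing silently;
  degenerate outcomes produce an explicit fit-failure record. Effects are
  exp(β) with 95% CIs.
* Subsidy status: multinomial logistic with nonsubsidized as the outcome
  reference and private housing as the exposure reference, reporting odds
  ratios per housing group for both contrasts. RSR: ordinary least
  squares, additive β per housing group. An empty status × housing cell
  raises a warning; categories are never collapsed automatically.
* Pearson chi-square (no continuity correction; df = (r−1)(c−1), with an
  error naming any empty margin) and Kruskal–Wallis (tie-corrected,
  df = groups − 1; a fully degenerate pooled sample returns statistic 0
  by convention, which scipy treats as an error case).

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions used throughout the
test-bed: 5000 patients, window 2005-01-01 … 2013-12-31, coding cut-over
2010-01-01, base year 2015.

A 3-level latent complexity tier (probabilities 0.60/0.30/0.10) jointly
drives per-class visit counts (negative binomial, e.g. inpatient means
0.25/1.2/3.0; size 1.5 — matching the count-model family by design,
documented as a self-consistency choice), drug counts (Poisson means
1.5/4/8), charge scale, and the severity mix of diagnosis codes — the
minimal structure under which CCI, PPS and utilization must correlate.
Housing groups are drawn with realistic mass (4-room most common, 18%
missing), and both the per-visit subsidy probability (0.85 down to 0.44)
and the subsidized bill fraction (Beta around 0.62 down to 0.35) fall
with housing size, building in the housing × subsidy dependence and the
monotone RSR gradient the harness must detect. Conversion routes for
randomly drawn codes follow configured mixes (ICD-10 era:
84/4/3/9% direct/zero/truncated/unmapped; ICD-9→CCS era: 88/7/3/2%),
with each route forced by construction of the ~60-key fixture crosswalks.
Planted rule violators (6 patients with under-21 visits, 8 pre-window
inpatient stays, 10 patients without a primary diagnosis, 7 born 1900,
9 males with a pregnancy code) are disjoint by construction so every
exclusion rule removes exactly its ledgered count.

What passing tests on this substrate show: the algorithms implement their
contracts exactly (routes, exclusion accounting, aggregation
conservation) and the statistical harness recovers planted structure at
realistic scale. What they do not show: performance on real coding
practice (the fixture crosswalks are tiny and clean; real backward maps
have thousands of keys, richer ambiguity, and coder idiosyncrasies), real
Singaporean epidemiology or billing magnitudes, or informative
missingness — postal-code missingness here is random given housing group,
whereas in real data it concentrates in non-resident patients.

## Problem sizes and numerical choices

The package's reference scale for end-to-end checks is 5000 patients
(≈44 000 visits, ≈80 000 diagnoses), which a single CPU processes in
under a minute; statistical-recovery checks use direct simulation from
the fitted model families (100 replicates at n=2000 for count models,
100 at n=20 000 for the multinomial model, 200 null replicates at
n=1000). Aggregation equality is asserted to 1e-6 relative tolerance;
floating charges are kept at full precision internally and rounded only
in reports. All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical config + seed reproduces the
tables byte for byte.

## Known limitations

* The conversion engine is table-agnostic but ships only fixture
  crosswalks; licensed ACCD / AHRQ CCS tables must be supplied by the
  user in the two-column format.
* Forward mapping (ICD-9 → ICD-10) is out of scope by design.
* Clinical adjudication of modified-code validity is a human process; the
  package only implements the audit arithmetic.
* The multinomial model offers no random effects or clustering; patients
  are treated as independent.
* Housing information is static (latest postal code only), and the DRG
  table of the source EMR layout is not consumed.
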