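# Methods

## Problem and model

Administrative and clinical data under-document chronic disease: a patient
can have hypertension without a billing code, a problem-list entry, or even
a recorded blood pressure. `htngap` quantifies that under-documentation by
comparing the prevalence a population's composition *predicts* with the
prevalence its records *show*.

**Eligibility.** The analyzable population is patients aged 18–85 at the
start of the observation year with at least one ambulatory evaluation-and-
management encounter dated within that calendar year. Age is materialized
as age at January 1 of the observation year and stored directly (no birth
dates); all date logic is calendar-date only.

**Observed prevalence** is defined at three cumulative evidence levels.
A patient's hypertension *tier* is the first matching of:

1. `claims` — any in-year ICD-10-CM hypertension code on a billing claim;
2. `problem_list` — any in-year hypertension code on the EHR problem list;
3. `bp_criteria` — office BP with one reading ≥160/100 mm Hg, or readings
   ≥140/90 mm Hg on two distinct calendar days (both cuts interpreted as
   systolic-OR-diastolic exceedance; an AND mode is available via
   `CodeSets.bp_require_both` for sensitivity analysis);
4. `none` otherwise.

Observed prevalence at level *k* is the share of eligible patients whose
tier is among the first *k* tiers, so the three estimates are nested and
non-decreasing by construction. Tiers 1–2 are documented diagnoses; tier 3
flags patients who meet screening criteria but may not have hypertension on
confirmation — the package reports it as part of the widest definition,
never as a diagnosis.

**Comorbidity ascertainment** (obesity, diabetes, CKD) mirrors the tiers:
claims code → problem-list code → clinical criterion, recorded as the
earliest level at which the condition is seen. Clinical criteria: any BMI
≥30 kg/m²; any HbA1c ≥6.5 % or fasting glucose ≥126 mg/dL on two distinct
dates; two eGFR <60 mL/min/1.73 m² at least 90 days apart (chronicity).
Code lists are prefix matches on undotted ICD-10-CM strings with defaults
hypertension {I10, I11, I12, I13, I15, I16}, obesity {E66}, diabetes
{E10, E11}, CKD {N18}. These follow common claims-algorithm practice;
they are *site policy*, shipped as an overridable `CodeSets` YAML, because
published applications rarely print their exact lists.

**Predicted (expected) prevalence** is indirect standardization. With
weights `w_s` giving the analyzed population's composition over strata
`s` — sex × race/ethnicity (4 known categories) × age group (18–44, 45–64,
65–74, 75–85), optionally × comorbidity-count bucket (0, 1, 2–3) — and a
reference table of stratum prevalences `π_s` with standard errors:

```
v = Σ_s w_s π_s        se(v) = sqrt(Σ_s w_s² se_s²)       CI = v ± 1.96·se(v)
```

The CI method is a package choice (reference-SE propagation); a Wald
interval on the organization's own denominator is selectable
(`ci_method="wald"`) for reference tables without SEs. Patients with
missing race/ethnicity are redistributed proportionally over the known
race categories observed within their sex × age cell (falling back to the
cohort-wide known-race distribution, then uniform); this keeps weights
normalized without inventing a "missing" reference stratum. An alternative
would map missing → "other"; proportional redistribution was chosen
because it is unbiased when missingness is unrelated to race within cells,
which is exactly how the synthetic generator models it.

Two comorbidity modes are provided. *Organization mode* builds joint
weights from patient-level ascertained comorbidity buckets at the chosen
evidence level. *Reference mode* uses demographic-only weights against a
table whose bucket dimension has been folded out with the reference
population's own bucket shares (`π_demo = Σ_b q_b π_{demo,b}`, SEs folded
in quadrature) — the fallback for organizations that cannot supply their
own comorbidity data. `tool_compatibility_weights` additionally emulates
feeding the published estimator summary marginals (demographics ×
bucket, joined under independence) instead of patient-level data; whether
the published spreadsheet tool multiplies marginals or uses a joint table
internally is not documented, so both routes exist.

**Gap report.** `diff_pp = 100·(v − observed)`; the difference CI applies
the predicted CI around the observed value, because observed prevalence is
a census of the analyzed population (no sampling), which is also why no
significance test is attached. Additional patients = `n·(v − observed)`,
reported signed and rounded to the nearest thousand (halves away from
zero); "one in N" = `round(100·v / diff_pp)`, undefined for non-positive
gaps. Display rounding throughout: prevalences and differences to 1
decimal, counts to the nearest thousand, totals to 2-decimal millions.

## Synthetic cohort generator

The generator emulates a multi-organization U.S. ambulatory population
with known truth, so recovery of the gap can be verified exactly.

Per patient: a demographic stratum is drawn from a configurable joint mix
(default: the product of published marginals — 57.3 % female; race/
ethnicity 73.9/7.1/3.4/10.5 % with 5.1 % missing; age bands
34.2/39.5/16.9/9.4 %). Patients recorded as race-missing carry a latent
known race drawn from their sex × age cell's conditional mix, which makes
the estimator's proportional redistribution well-calibrated by
construction. True hypertension and comorbidity statuses are Bernoulli
draws from stratum-specific prevalences; defaults are age-graded
(hypertension 15/42/62/72 % across the four bands, +6 pp for non-Hispanic
Black patients, capped at 95 %; obesity 38/49/47/38 %; diabetes
7/18/28/30 %; CKD 1/5/15/30 %), chosen as realistic primary-care gradients
whose population totals land near the richest-evidence estimates of the
emulated application (~39 % expected hypertension, ~45/16/7 % comorbidity).

Documentation is layered: a true case receives an in-year claim code with
probability `claims_sensitivity` (defaults 0.74 hypertension, 0.24
obesity, 0.69 diabetes, 0.46 CKD), otherwise a problem-list code with
probability `problem_list_increment` (0.09/0.07/0.31/0.25); qualifying
clinical evidence is recorded with `clinical_documentation_rate`
(0.93/0.75/0.60), with unremarkable values recorded at the same rate for
non-cases so measurement presence does not leak the label. CKD truth
writes two sub-threshold eGFRs ≥90 days apart (the chronicity rule must be
satisfiable). Visits follow a configurable count distribution (default
mean ≈2.8, support 1–6); the first visit is always ambulatory E&M so
generated patients are eligible. Office BP is one reading per visit,
normal around 150/92 (true hypertensives) or 118/74 mm Hg with visit-level
SD 12/8 — so some normotensives cross thresholds by noise and some
hypertensives are missed, as in practice; 5.9 % of patients (default)
have no BP recorded at all. Per-organization multiplicative tilts
(default U(0.85, 1.10)) on claim/problem-list sensitivity create
cross-organization spread in observed prevalence; clinical recording is
left untilted. Randomness is keyed per patient by `(seed, patient index)`
via independent bit-generator streams, so enlarging a cohort never
perturbs existing patients.

`generate_reference_table` returns the table implied by the generator's
own truth: every comorbidity bucket inherits its demographic stratum's
hypertension prevalence (truth is assigned independently of comorbidities
given the stratum — a documented simplification), bucket shares follow in
closed form from independent condition draws, and SEs are binomial on a
configurable pseudo-survey size (default 5,000 per stratum).

What the generator does *not* emulate: correlation between hypertension
and comorbidities within a stratum (so the two comorbidity modes agree on
synthetic data and only diverge on real data), disease progression,
treatment effects on BP, coding errors/false-positive codes, and visit
patterns that depend on health status. Passing tests therefore validate
the *pipeline arithmetic and definitions*, not the realism of any
particular documentation-sensitivity value.

## Numerical and engineering choices

- Dates: ISO-8601 strings in CSV; all comparisons at calendar-day
  resolution. "Two readings on different days" means distinct calendar
  dates within the observation year.
- Tier precedence is claims > problem list > BP, matching the sequential
  construction of the case definitions; counts by tier partition the
  eligible set.
- Rounding uses halves-away-from-zero (not banker's) wherever a printed
  convention is reproduced.
- Validation is collect-then-fail: `read_cohort` reports every violating
  row with file and row number rather than stopping at the first.
- The acceptance and analysis runs use 50,000-patient cohorts across 25
  organizations, and unit-level Monte-Carlo checks use 5,000–30,000
  patients with 3-standard-error tolerances — sizes at which binomial noise
  is well below the effects being checked.
- Reference tables are validated for completeness (all 32 demographic
  strata, × 3 buckets in joint mode) at construction; a missing stratum is
  an error at prediction time, never silently skipped.
- The packaged reference-style data under `htngap/data/` are the printed
  *summary* estimates of the 2016 multi-organization application; no
  survey-based stratum table is fabricated, and users must supply their
  own reference table for real analyses.

## Known limitations

- BP criteria identify screening-positive patients, not confirmed
  diagnoses; office readings also overestimate standardized BP, and no
  measurement-bias adjustment is applied.
- The estimator inherits whatever bias the reference table carries; no
  refitting or small-area machinery is included.
- Problem-list entries are taken at face value within the observation year
  (no active/resolved status); medication-based ascertainment is out of
  scope.
- The cross-organization *range* of gaps is sensitive to small
  organizations; only extrema are reported, with no uncertainty attached.
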