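# htngap

Estimating **undiagnosed hypertension** from routine health-care data.

Health care delivery organizations can compare the hypertension prevalence
they *observe* in billing and EHR data against the prevalence their patient
mix *predicts* (the mechanism of the CDC Million Hearts Hypertension
Prevalence Estimator): when predicted exceeds observed, the difference
flags patients who plausibly have hypertension but no documented diagnosis.
`htngap` implements that workflow end to end for analysts working with
claims/EHR extracts:

1. **Nested case definitions.** A patient is observed hypertensive by, in
   order of precedence: an ICD-10-CM hypertension code on a billing
   **claim**; a hypertension code on the EHR **problem list**; or elevated
   office **blood pressure** — one reading ≥160/100 mm Hg, or readings
   ≥140/90 mm Hg on two different calendar days. The three cumulative
   evidence levels (claims; claims or problem list; plus BP criteria) give
   nested observed prevalences. Comorbidities (obesity, diabetes, chronic
   kidney disease) are ascertained analogously from claims, problem list,
   or clinical measurements (BMI ≥30 kg/m²; HbA1c ≥6.5 % or fasting glucose
   ≥126 mg/dL twice; eGFR <60 mL/min/1.73 m² twice ≥90 days apart).
2. **Expected prevalence by indirect standardization.** With population
   weights `w_s` over strata `s` (sex × race/ethnicity × age group,
   optionally × comorbidity-count bucket 0/1/2–3) and reference stratum
   prevalences `π_s` with standard errors `se_s`:

   `v = Σ_s w_s π_s`,  `se(v) = sqrt(Σ_s w_s² se_s²)`,  95 % CI `v ± 1.96 se(v)`.

3. **Gap reporting.** Percentage-point difference `100·(v − observed)`,
   the implied count of additional (potentially undiagnosed) patients, and
   the "one in N" ratio among patients predicted hypertensive — overall and
   per organization — plus the BP-screening gap (eligible patients with no
   BP reading on file).
4. **A synthetic cohort generator** with known ground truth (true
   hypertension status, per-source documentation sensitivity, visit-level
   BP noise, measurement missingness), so every stage is validated against
   a cohort whose right answer is known.

## Worked example

```bash
htngap simulate --n 20000 --orgs 5 --seed 1 --out scratch/demo
htngap gap --cohort scratch/demo --reference scratch/demo/reference_table.csv \
           --reference-buckets scratch/demo/reference_buckets.csv --out scratch/demo_gap.csv
```

Or via the numbered analysis (50,000 patients, 25 organizations):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_ascertain_hypertension.py
python analysis/04_gap_report.py
```

which prints, for the default study conditions:

```
observed prevalence at claims_only: 27.9%
observed prevalence at plus_problem_list: 28.9%
observed prevalence at plus_clinical: 37.7%
BP-screening gap: 5.9% of eligible patients have no BP reading (org range 5.1-6.9%)
claims_only: observed 27.9% vs predicted 39.4% -> gap 11.5 pp, 6,000 additional patients (one in 3)
plus_clinical: observed 37.7% vs predicted 39.4% -> gap 1.7 pp, 1,000 additional patients (one in 23)
cross-org gap range at claims_only: 9.0 to 15.6 pp
```

Reading this: billing claims alone document only ~28 % of the population as
hypertensive while the demographic/comorbidity mix predicts ~39 %; adding
problem-list codes and BP criteria closes most — but not all — of that gap.
The remaining 1.7 pp at the richest evidence level are patients whose
records carry no sign of the hypertension the generator actually gave them
(undocumented cases), which the pipeline correctly sizes: on synthetic
data the recovered gap matches the generator's withheld-diagnosis count
(see `tests/test_acceptance.py`).

`analysis/05_published_arithmetic.py` runs the same gap arithmetic on the
printed summary estimates of the 2016 application of the estimator tool to
8.92 million patients across 25 organizations (packaged in
`htngap/data/`), reproducing its derived quantities — e.g. a 4.1 pp gap /
366,000 additional patients at the claims level, one-in-8 to one-in-11
ratios, and a cross-organization maximum gap of 13.8 pp at the all-data
level. Those patient-level data are proprietary, so the printed
prevalences enter only as fixed inputs to arithmetic.

## Layout

- `src/htngap/` — the library: `cohort` (types, CSV I/O, eligibility,
  demographics), `simulate` (synthetic cohorts + reference tables),
  `ascertain` (case definitions), `estimator` (indirect standardization),
  `gap` (comparison report), `pipeline`/`cli` (config-driven runs),
  `published` (printed summary estimates of the 2016 application).
- `analysis/` — numbered narrative drivers writing small tables to `results/`.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
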