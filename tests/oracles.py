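"""Independent brute-force implementations used to cross-check the package.

Everything here is deliberately naive (per-patient python loops over raw
row tuples, no pandas grouping, no shared code with htngap.ascertain) so
it can serve as an oracle for the vectorized implementations.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from htngap.cohort import Cohort


def tier_oracle(dx_rows, bp_rows, year, code_sets) -> str:
    """dx_rows: (date, code, source); bp_rows: (date, systolic, diastolic)."""
    def undot(code):
        return code.upper().replace(".", "")

    def matches(code, prefixes):
        return any(undot(code).startswith(p.upper().replace(".", "")) for p in prefixes)

    dx = [(d, c, s) for (d, c, s) in dx_rows if pd.Timestamp(d).year == year]
    bp = [(d, s, di) for (d, s, di) in bp_rows if pd.Timestamp(d).year == year]
    if any(matches(c, code_sets.hypertension_prefixes) and s == "claim" for _, c, s in dx):
        return "claims"
    if any(matches(c, code_sets.hypertension_prefixes) and s == "problem_list" for _, c, s in dx):
        return "problem_list"

    def exceeds(s, d, cut):
        if code_sets.bp_require_both:
            return s >= cut[0] and d >= cut[1]
        return s >= cut[0] or d >= cut[1]

    if any(exceeds(s, d, code_sets.bp_single) for _, s, d in bp):
        return "bp_criteria"
    days = {pd.Timestamp(t).date() for t, s, d in bp if exceeds(s, d, code_sets.bp_repeat)}
    if len(days) >= 2:
        return "bp_criteria"
    return "none"


def flags_oracle(dx_rows, meas_rows, year, code_sets) -> dict[str, str]:
    """meas_rows: (date, kind, value). Returns condition -> level or 'none'."""
    def undot(code):
        return code.upper().replace(".", "")

    def matches(code, prefixes):
        return any(undot(code).startswith(p.upper().replace(".", "")) for p in prefixes)

    dx = [(d, c, s) for (d, c, s) in dx_rows if pd.Timestamp(d).year == year]
    meas = [(d, k, v) for (d, k, v) in meas_rows if pd.Timestamp(d).year == year]
    out = {}
    for cond in ("obesity", "diabetes", "ckd"):
        prefixes = code_sets.prefixes(cond)
        if any(matches(c, prefixes) and s == "claim" for _, c, s in dx):
            out[cond] = "claims_only"
            continue
        if any(matches(c, prefixes) and s == "problem_list" for _, c, s in dx):
            out[cond] = "plus_problem_list"
            continue
        if cond == "obesity":
            clin = any(k == "bmi" and v >= code_sets.bmi_cut for _, k, v in meas)
        elif cond == "diabetes":
            a1c = any(k == "hba1c" and v >= code_sets.hba1c_cut for _, k, v in meas)
            glu_days = {pd.Timestamp(d).date() for d, k, v in meas
                        if k == "fasting_glucose" and v >= code_sets.fasting_glucose_cut}
            clin = a1c or len(glu_days) >= 2
        else:
            low = sorted(pd.Timestamp(d).date() for d, k, v in meas
                         if k == "egfr" and v < code_sets.egfr_cut)
            clin = any((b - a).days >= code_sets.egfr_chronicity_days
                       for a in low for b in low)
        out[cond] = "plus_clinical" if clin else "none"
    return out


def expectation_oracle(stratum_keys, pi_map) -> float:
    """Patient-level expected prevalence: assign each patient their stratum's
    prevalence and average."""
    return sum(pi_map[k][0] if isinstance(pi_map[k], tuple) else pi_map[k]
               for k in stratum_keys) / len(stratum_keys)


def random_raw_cohort(rng: np.random.Generator, n_max: int = 200,
                      year: int = 2016) -> Cohort:
    """A messy random cohort: mixed ages (some ineligible), mixed encounter
    years/settings, random diagnosis codes/sources, BP readings and
    measurements straddling thresholds. Built row-by-row, independent of
    the package's generator."""
    n = int(rng.integers(3, n_max + 1))
    codes = ["I10", "I11.0", "I12.9", "I15.0", "E66.9", "E66.01", "E10.9",
             "E11.65", "N18.3", "N18.9", "J45.0", "K21.9", "I50.9"]
    patients, encounters, dx, bp, meas = [], [], [], [], []
    for i in range(n):
        pid = f"r{i:04d}"
        age = int(rng.integers(10, 96))
        sex = ["female", "male"][int(rng.integers(2))]
        race = ["nh_white", "nh_black", "hispanic", "other", "missing"][int(rng.integers(5))]
        org = f"org{int(rng.integers(3)) + 1}"
        patients.append((pid, org, sex, age, race))
        for _ in range(int(rng.integers(0, 4))):
            y = int(rng.choice([year - 1, year, year], p=[0.15, 0.425, 0.425]))
            day = int(rng.integers(0, 365))
            setting = "ambulatory_em" if rng.random() < 0.8 else "other"
            encounters.append((pid, pd.Timestamp(f"{y}-01-01") + pd.Timedelta(days=day),
                               setting))
        for _ in range(int(rng.integers(0, 4))):
            y = year - 1 if rng.random() < 0.15 else year
            day = int(rng.integers(0, 365))
            source = "claim" if rng.random() < 0.5 else "problem_list"
            dx.append((pid, pd.Timestamp(f"{y}-01-01") + pd.Timedelta(days=day),
                       codes[int(rng.integers(len(codes)))], source))
        for _ in range(int(rng.integers(0, 4))):
            day = int(rng.integers(0, 365))
            s = int(rng.integers(100, 200))
            d = int(rng.integers(60, min(s, 120)))
            bp.append((pid, pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=day), s, d))
        for _ in range(int(rng.integers(0, 4))):
            day = int(rng.integers(0, 365))
            kind = ["bmi", "hba1c", "fasting_glucose", "egfr"][int(rng.integers(4))]
            value = {"bmi": rng.uniform(20, 40), "hba1c": rng.uniform(4.5, 9.5),
                     "fasting_glucose": rng.uniform(80, 200),
                     "egfr": rng.uniform(20, 110)}[kind]
            meas.append((pid, pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=day),
                         kind, round(float(value), 1)))
    return Cohort(
        patients=pd.DataFrame(patients, columns=["patient_id", "org_id", "sex", "age",
                                                 "race_ethnicity"]),
        encounters=pd.DataFrame(encounters, columns=["patient_id", "date", "setting"]),
        diagnoses=pd.DataFrame(dx, columns=["patient_id", "date", "code", "source"]),
        bp_readings=pd.DataFrame(bp, columns=["patient_id", "date", "systolic", "diastolic"]),
        measurements=pd.DataFrame(meas, columns=["patient_id", "date", "kind", "value"]),
        observation_year=year,
    )
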