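"""Nested case definitions for hypertension and three-source comorbidity rules.

Hypertension is ascertained in mutually exclusive tiers, each using more
data than the last: a billing-claim diagnosis code; failing that, a problem
list code; failing that, elevated office blood pressure (one reading at or
above the severe cut, or readings at or above the stage-2 cut on two
different calendar days). Comorbidities (obesity, diabetes, CKD) are
ascertained at the earliest of three cumulative evidence levels: claims
code, problem-list code, or a clinical criterion on recorded measurements.

All evidence is restricted to the cohort's observation year.
"""
from __future__ import annotations

import math
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codesets import CodeSets, DEFAULT_CODE_SETS
from .cohort import Cohort
from .types import (ADMISSIBLE_TIERS, BUCKETS, CONDITIONS, LEVELS, LEVEL_RANK,
                    PrevalenceEstimate, count_bucket)

_Z95 = 1.959963984540054


def _undot(codes: pd.Series) -> pd.Series:
    return codes.astype(str).str.upper().str.replace(".", "", regex=False)


def _prefix_regex(prefixes: Sequence[str]) -> str:
    parts = sorted({p.replace(".", "").upper() for p in prefixes})
    return "^(?:" + "|".join(re.escape(p) for p in parts) + ")"


def _reading_exceeds(systolic, diastolic, cut: tuple[int, int], require_both: bool):
    s_ok = np.asarray(systolic) >= cut[0]
    d_ok = np.asarray(diastolic) >= cut[1]
    return (s_ok & d_ok) if require_both else (s_ok | d_ok)


def bp_criteria_met(readings: Iterable[tuple], code_sets: CodeSets = DEFAULT_CODE_SETS) -> bool:
    """Office-BP case criterion for a single patient's in-year readings.

    ``readings`` is an iterable of ``(date, systolic, diastolic)``. True iff
    one reading is at/above the single-reading cut (default 160/100) or
    readings on two distinct calendar dates are at/above the repeat cut
    (default 140/90). An empty list is False.
    """
    rows = list(readings)
    if not rows:
        return False
    dates = [pd.Timestamp(d).date() for d, _, _ in rows]
    sys_ = np.array([s for _, s, _ in rows], dtype=float)
    dia = np.array([d for _, _, d in rows], dtype=float)
    if _reading_exceeds(sys_, dia, code_sets.bp_single, code_sets.bp_require_both).any():
        return True
    rep = _reading_exceeds(sys_, dia, code_sets.bp_repeat, code_sets.bp_require_both)
    qualifying_days = {day for day, ok in zip(dates, rep) if ok}
    return len(qualifying_days) >= 2


def _in_year(df: pd.DataFrame, year: int) -> pd.DataFrame:
    if not len(df):
        return df
    return df[pd.to_datetime(df["date"]).dt.year == year]


def ascertain(cohort: Cohort, eligible: Iterable[str],
              code_sets: CodeSets = DEFAULT_CODE_SETS) -> pd.DataFrame:
    """Per-patient ascertainment table for all eligible patients.

    Columns: patient_id, htn_tier (claims | problem_list | bp_criteria |
    none) and, per condition, the earliest evidence level at which it is
    ascertained (claims_only | plus_problem_list | plus_clinical | none).
    """
    eligible = sorted(set(eligible))
    year = cohort.observation_year
    dx = _in_year(cohort.diagnoses, year)
    dx = dx[dx["patient_id"].isin(eligible)]
    codes = _undot(dx["code"]) if len(dx) else pd.Series(dtype=str)

    def code_ids(prefixes, source) -> set[str]:
        if not len(dx):
            return set()
        mask = codes.str.match(_prefix_regex(prefixes)) & (dx["source"] == source)
        return set(dx.loc[mask.to_numpy(), "patient_id"])

    htn_claim = code_ids(code_sets.hypertension_prefixes, "claim")
    htn_pl = code_ids(code_sets.hypertension_prefixes, "problem_list")

    bp = _in_year(cohort.bp_readings, year)
    bp = bp[bp["patient_id"].isin(eligible)]
    bp_ids: set[str] = set()
    if len(bp):
        single = _reading_exceeds(bp["systolic"], bp["diastolic"],
                                  code_sets.bp_single, code_sets.bp_require_both)
        bp_ids |= set(bp.loc[single, "patient_id"])
        rep = _reading_exceeds(bp["systolic"], bp["diastolic"],
                               code_sets.bp_repeat, code_sets.bp_require_both)
        rep_bp = bp.loc[rep]
        if len(rep_bp):
            days = rep_bp.groupby("patient_id")["date"].nunique()
            bp_ids |= set(days.index[days >= 2])

    meas = _in_year(cohort.measurements, year)
    meas = meas[meas["patient_id"].isin(eligible)]

    def clinical_ids(condition: str) -> set[str]:
        if not len(meas):
            return set()
        if condition == "obesity":
            m = meas[(meas["kind"] == "bmi") & (meas["value"] >= code_sets.bmi_cut)]
            return set(m["patient_id"])
        if condition == "diabetes":
            a1c = meas[(meas["kind"] == "hba1c") & (meas["value"] >= code_sets.hba1c_cut)]
            ids = set(a1c["patient_id"])
            glu = meas[(meas["kind"] == "fasting_glucose")
                       & (meas["value"] >= code_sets.fasting_glucose_cut)]
            if len(glu):
                days = glu.groupby("patient_id")["date"].nunique()
                ids |= set(days.index[days >= 2])
            return ids
        if condition == "ckd":
            low = meas[(meas["kind"] == "egfr") & (meas["value"] < code_sets.egfr_cut)]
            if not len(low):
                return set()
            g = low.groupby("patient_id")["date"]
            span = (g.max() - g.min()).dt.days
            return set(span.index[span >= code_sets.egfr_chronicity_days])
        raise KeyError(condition)

    out = pd.DataFrame({"patient_id": eligible})
    tier = np.full(len(out), "none", dtype=object)
    tier[out["patient_id"].isin(bp_ids)] = "bp_criteria"
    tier[out["patient_id"].isin(htn_pl)] = "problem_list"
    tier[out["patient_id"].isin(htn_claim)] = "claims"
    out["htn_tier"] = tier

    for cond in CONDITIONS:
        claim_ids = code_ids(code_sets.prefixes(cond), "claim")
        pl_ids = code_ids(code_sets.prefixes(cond), "problem_list")
        clin_ids = clinical_ids(cond)
        level = np.full(len(out), "none", dtype=object)
        level[out["patient_id"].isin(clin_ids)] = "plus_clinical"
        level[out["patient_id"].isin(pl_ids)] = "plus_problem_list"
        level[out["patient_id"].isin(claim_ids)] = "claims_only"
        out[f"{cond}_level"] = level
    return out


def hypertension_tier(diagnoses: pd.DataFrame, readings: Iterable[tuple],
                      code_sets: CodeSets = DEFAULT_CODE_SETS) -> str:
    """Tier for one patient from in-year diagnosis rows and BP readings."""
    if len(diagnoses):
        codes = _undot(diagnoses["code"])
        hit = codes.str.match(_prefix_regex(code_sets.hypertension_prefixes))
        if (hit & (diagnoses["source"] == "claim")).any():
            return "claims"
        if (hit & (diagnoses["source"] == "problem_list")).any():
            return "problem_list"
    if bp_criteria_met(readings, code_sets):
        return "bp_criteria"
    return "none"


def condition_flags(diagnoses: pd.DataFrame, measurements: pd.DataFrame,
                    code_sets: CodeSets = DEFAULT_CODE_SETS) -> dict[str, str]:
    """Earliest evidence level per condition for one patient.

    Returns ``{condition: level-or-"none"}``; clinical criteria are
    BMI >= cut (obesity), HbA1c >= cut or fasting glucose >= cut on two
    distinct dates (diabetes), and two eGFR < cut at least the chronicity
    window apart (CKD).
    """
    out: dict[str, str] = {}
    codes = _undot(diagnoses["code"]) if len(diagnoses) else pd.Series(dtype=str)
    for cond in CONDITIONS:
        level = "none"
        if len(measurements):
            if cond == "obesity":
                sel = measurements[(measurements["kind"] == "bmi")
                                   & (measurements["value"] >= code_sets.bmi_cut)]
                clin = len(sel) > 0
            elif cond == "diabetes":
                a1c = measurements[(measurements["kind"] == "hba1c")
                                   & (measurements["value"] >= code_sets.hba1c_cut)]
                glu = measurements[(measurements["kind"] == "fasting_glucose")
                                   & (measurements["value"] >= code_sets.fasting_glucose_cut)]
                clin = len(a1c) > 0 or glu["date"].nunique() >= 2
            else:
                low = measurements[(measurements["kind"] == "egfr")
                                   & (measurements["value"] < code_sets.egfr_cut)]
                clin = (len(low) >= 2 and (low["date"].max() - low["date"].min()).days
                        >= code_sets.egfr_chronicity_days)
            if clin:
                level = "plus_clinical"
        if len(diagnoses):
            hit = codes.str.match(_prefix_regex(code_sets.prefixes(cond)))
            if (hit & (diagnoses["source"] == "problem_list")).any():
                level = "plus_problem_list"
            if (hit & (diagnoses["source"] == "claim")).any():
                level = "claims_only"
        out[cond] = level
    return out


def _wald_ci(p: float, n: int) -> tuple[float, float]:
    se = math.sqrt(max(p * (1.0 - p), 0.0) / n) if n else 0.0
    return max(0.0, p - _Z95 * se), min(1.0, p + _Z95 * se)


def observed_prevalence(cohort: Cohort, eligible: Iterable[str], level: str,
                        code_sets: CodeSets = DEFAULT_CODE_SETS,
                        ascertainment: pd.DataFrame | None = None) -> PrevalenceEstimate:
    """Observed hypertension prevalence among eligible patients at an evidence level."""
    eligible = set(eligible)
    if not eligible:
        raise ValueError("eligible set is empty")
    if level not in LEVELS:
        raise KeyError(f"unknown evidence level {level!r}")
    if ascertainment is None:
        ascertainment = ascertain(cohort, eligible, code_sets)
    sub = ascertainment[ascertainment["patient_id"].isin(eligible)]
    n = len(eligible)
    k = int(sub["htn_tier"].isin(ADMISSIBLE_TIERS[level]).sum())
    p = k / n
    lo, hi = _wald_ci(p, n)
    return PrevalenceEstimate(value=p, ci_low=lo, ci_high=hi, n=n)


def level_ascertained(asc: pd.DataFrame, condition: str, level: str) -> pd.Series:
    """Boolean series: condition ascertained at or before ``level`` (cumulative)."""
    col = asc[f"{condition}_level"]
    rank = col.map(lambda v: LEVEL_RANK.get(v, len(LEVELS)))
    return rank <= LEVEL_RANK[level]


def comorbidity_distribution(cohort: Cohort, eligible: Iterable[str], level: str,
                             code_sets: CodeSets = DEFAULT_CODE_SETS,
                             ascertainment: pd.DataFrame | None = None) -> dict:
    """Count-bucket shares and per-condition prevalences at an evidence level.

    Returns ``{"buckets": {zero, one, two_or_three: share},
    "conditions": {condition: prevalence}}``; bucket shares sum to 1.
    """
    eligible = set(eligible)
    if not eligible:
        raise ValueError("eligible set is empty")
    if ascertainment is None:
        ascertainment = ascertain(cohort, eligible, code_sets)
    sub = ascertainment[ascertainment["patient_id"].isin(eligible)]
    n = len(sub)
    flags = pd.DataFrame({c: level_ascertained(sub, c, level) for c in CONDITIONS})
    counts = flags.sum(axis=1)
    buckets = counts.map(count_bucket).value_counts()
    return {
        "buckets": {b: float(buckets.get(b, 0)) / n for b in BUCKETS},
        "conditions": {c: float(flags[c].mean()) for c in CONDITIONS},
    }


def bp_screening_gap(cohort: Cohort, eligible: Iterable[str]) -> tuple[float, pd.Series]:
    """Share of eligible patients with no in-year BP reading, overall and per org."""
    eligible = set(eligible)
    if not eligible:
        raise ValueError("eligible set is empty")
    bp = _in_year(cohort.bp_readings, cohort.observation_year)
    with_bp = set(bp["patient_id"]) & eligible
    pat = cohort.patients
    sub = pat[pat["patient_id"].isin(eligible)].copy()
    sub["no_bp"] = ~sub["patient_id"].isin(with_bp)
    overall = float(sub["no_bp"].mean())
    per_org = sub.groupby("org_id")["no_bp"].mean()
    return overall, per_org
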