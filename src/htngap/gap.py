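"""Observed-vs-predicted prevalence comparison: the undiagnosed-gap report.

The headline quantities: the percentage-point difference between predicted
(expected) and observed hypertension prevalence, the implied number of
additional — potentially undiagnosed — patients, and the "one in N" ratio
among patients predicted to have hypertension. Observed prevalence is a
census quantity (the whole population is enumerated), so the difference CI
comes from the predicted estimate alone.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import ascertain as asc_mod
from . import estimator as est_mod
from .codesets import CodeSets, DEFAULT_CODE_SETS
from .cohort import Cohort, eligible_patients
from .types import LEVELS, PrevalenceEstimate

#: Comorbidity sourcing for the prediction: the organization's own
#: ascertained comorbidity data, or the reference population's.
MODES = ("org_comorbidity", "reference_comorbidity")


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5) if x >= 0 else -math.floor(-x + 0.5)


def round_to_thousand(x: float) -> int:
    """Round to the nearest thousand, halves away from zero."""
    return _round_half_up(x / 1000.0) * 1000


def millions2(count: float) -> float:
    """A patient count as millions with two decimals (display convention)."""
    return _round_half_up(count / 10_000.0) / 100.0


@dataclass
class GapReport:
    """Observed vs predicted comparison for one population and configuration."""

    org_id: str
    level: str | None
    comorbidity_mode: str | None
    observed: PrevalenceEstimate
    predicted: PrevalenceEstimate
    diff_pp: float               # 100 * (predicted - observed)
    diff_ci: tuple[float, float]  # percentage points
    additional_raw: float        # n * (predicted - observed), signed
    additional_patients: int     # rounded to the nearest thousand, signed
    one_in_n: int | None         # None when the gap is not positive

    def to_row(self) -> dict:
        return {
            "org_id": self.org_id,
            "level": self.level,
            "comorbidity_mode": self.comorbidity_mode,
            "n": self.observed.n,
            "observed_pct": self.observed.pct,
            "predicted_pct": self.predicted.pct,
            "predicted_ci_low_pct": 100.0 * self.predicted.ci_low,
            "predicted_ci_high_pct": 100.0 * self.predicted.ci_high,
            "diff_pp": self.diff_pp,
            "diff_ci_low_pp": self.diff_ci[0],
            "diff_ci_high_pp": self.diff_ci[1],
            "additional_raw": self.additional_raw,
            "additional_patients": self.additional_patients,
            "one_in_n": self.one_in_n,
        }


def one_in_n(predicted_pct: float, diff_pp: float) -> int | None:
    """"One in N" patients predicted hypertensive who lack a diagnosis.

    ``round(predicted_pct / diff_pp)`` with halves away from zero; undefined
    (None) when the gap is not positive.
    """
    if diff_pp <= 0:
        return None
    return _round_half_up(predicted_pct / diff_pp)


def compare(observed: PrevalenceEstimate, predicted: PrevalenceEstimate, n: int,
            org_id: str = "overall", level: str | None = None,
            comorbidity_mode: str | None = None) -> GapReport:
    """Build a GapReport from an observed and a predicted prevalence estimate."""
    if n <= 0:
        raise ValueError("population size n must be positive")
    gap = predicted.value - observed.value
    diff_pp = 100.0 * gap
    diff_ci = (100.0 * (predicted.ci_low - observed.value),
               100.0 * (predicted.ci_high - observed.value))
    additional_raw = n * gap
    return GapReport(
        org_id=org_id, level=level, comorbidity_mode=comorbidity_mode,
        observed=observed, predicted=predicted,
        diff_pp=diff_pp, diff_ci=diff_ci,
        additional_raw=additional_raw,
        additional_patients=round_to_thousand(additional_raw),
        one_in_n=one_in_n(100.0 * predicted.value, diff_pp),
    )


def compare_percentages(observed_pct: float, predicted_pct: float, n: int,
                        predicted_ci_pct: tuple[float, float] | None = None,
                        **kwargs) -> GapReport:
    """Convenience wrapper taking printed percentages (e.g. published tables)."""
    lo, hi = predicted_ci_pct if predicted_ci_pct else (predicted_pct, predicted_pct)
    observed = PrevalenceEstimate(observed_pct / 100.0, observed_pct / 100.0,
                                  observed_pct / 100.0, n)
    predicted = PrevalenceEstimate(predicted_pct / 100.0, lo / 100.0, hi / 100.0, n)
    return compare(observed, predicted, n, **kwargs)


def _predict_for(cohort: Cohort, eligible: set, reference: est_mod.ReferenceTable,
                 level: str, mode: str, code_sets: CodeSets,
                 ascertainment: pd.DataFrame | None,
                 ci_method: str) -> PrevalenceEstimate:
    n = len(eligible)
    if mode == "org_comorbidity":
        if reference.mode != "joint":
            raise ValueError("org_comorbidity mode needs a joint reference table")
        w = est_mod.stratum_weights(cohort, eligible, level=level, use_comorbidity=True,
                                    code_sets=code_sets, ascertainment=ascertainment)
        return est_mod.predicted_prevalence(w, reference, n, ci_method=ci_method)
    if mode == "reference_comorbidity":
        table = (est_mod.fold_reference_comorbidity(reference)
                 if reference.mode == "joint" else reference)
        w = est_mod.stratum_weights(cohort, eligible, use_comorbidity=False,
                                    code_sets=code_sets)
        return est_mod.predicted_prevalence(w, table, n, ci_method=ci_method)
    raise KeyError(f"unknown comorbidity mode {mode!r}")


def cohort_gaps(cohort: Cohort, reference: est_mod.ReferenceTable,
                code_sets: CodeSets = DEFAULT_CODE_SETS,
                levels: Sequence[str] = LEVELS, modes: Sequence[str] = MODES,
                eligible: Iterable[str] | None = None,
                org_id: str = "overall",
                ci_method: str = "reference_se") -> list[GapReport]:
    """Overall gap reports for one population across levels and modes."""
    eligible = set(eligible) if eligible is not None else eligible_patients(cohort)
    if not eligible:
        raise ValueError("no eligible patients")
    asc = asc_mod.ascertain(cohort, eligible, code_sets)
    out = []
    for level in levels:
        observed = asc_mod.observed_prevalence(cohort, eligible, level, code_sets,
                                               ascertainment=asc)
        for mode in modes:
            predicted = _predict_for(cohort, eligible, reference, level, mode,
                                     code_sets, asc, ci_method)
            out.append(compare(observed, predicted, len(eligible), org_id=org_id,
                               level=level, comorbidity_mode=mode))
    return out


def per_org_gaps(cohort: Cohort, reference: est_mod.ReferenceTable,
                 code_sets: CodeSets = DEFAULT_CODE_SETS,
                 levels: Sequence[str] = LEVELS, modes: Sequence[str] = MODES,
                 ci_method: str = "reference_se") -> tuple[pd.DataFrame, dict]:
    """Gap reports per organization plus cross-organization extrema of diff_pp.

    Organizations with zero eligible patients are excluded (with a row in
    the returned extrema dict listing them). Returns ``(reports, extrema)``
    where ``extrema[(level, mode)] = {"min": ..., "max": ...}``.
    """
    eligible = eligible_patients(cohort)
    pat = cohort.patients
    orgs = sorted(pat["org_id"].unique())
    reports: list[GapReport] = []
    skipped = []
    for org in orgs:
        org_ids = set(pat.loc[pat["org_id"] == org, "patient_id"]) & eligible
        if not org_ids:
            skipped.append(org)
            continue
        reports += cohort_gaps(cohort, reference, code_sets, levels, modes,
                               eligible=org_ids, org_id=org, ci_method=ci_method)
    if not reports:
        raise ValueError("no organization has eligible patients")
    df = pd.DataFrame([r.to_row() for r in reports])
    extrema = {}
    for level in levels:
        for mode in modes:
            sel = df[(df["level"] == level) & (df["comorbidity_mode"] == mode)]["diff_pp"]
            extrema[(level, mode)] = {"min": float(sel.min()), "max": float(sel.max())}
    extrema["skipped_orgs"] = skipped
    return df, extrema


def gaps_from_prevalence_table(table: pd.DataFrame, n: int = 1) -> tuple[pd.DataFrame, dict]:
    """Gap arithmetic on an already-summarized prevalence table.

    ``table`` needs columns org_id, level, observed_pct, predicted_pct —
    e.g. published organization-level estimates. Returns per-row diff_pp
    plus cross-organization extrema per level.
    """
    rows = []
    for r in table.itertuples(index=False):
        rep = compare_percentages(r.observed_pct, r.predicted_pct, n,
                                  org_id=str(r.org_id), level=r.level)
        rows.append(rep.to_row())
    df = pd.DataFrame(rows)
    extrema = {
        level: {"min": float(sub["diff_pp"].min()), "max": float(sub["diff_pp"].max())}
        for level, sub in df.groupby("level")
    }
    return df, extrema
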