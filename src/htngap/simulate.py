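"""Synthetic EHR/claims cohort generator with known ground truth.

Emulates the data environment of a multi-organization primary-care
population: each patient has a demographic stratum, a latent true
hypertension status and true comorbidities (obesity, diabetes, CKD), and
the *documentation* of those conditions is imperfect and layered — a true
case receives a billing-claim code with some sensitivity, otherwise may
surface on the EHR problem list, and clinical evidence (office BP
readings, BMI, HbA1c, eGFR) is recorded with its own rate. Observed
prevalence at each evidence level is therefore below truth by
construction, which is exactly the gap the pipeline is built to measure.

Randomness is keyed per patient by ``(seed, patient index)``, so growing
a cohort leaves earlier patients' records unchanged.

Defaults mirror a 2016 U.S. multispecialty ambulatory population:
demographic mix from published marginals (57.3% female, 73.9% NH-white,
modal age 45-64), 5.9% of patients with no BP reading on file, and
documentation sensitivities that leave roughly a 3-4 percentage-point
observed-vs-expected hypertension gap at the richest evidence level.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import AGE_GROUPS, KNOWN_RACES, RACE_ETHNICITIES, SEXES, Cohort
from .estimator import ALL_BUCKETS, DEMO_KEYS, ReferenceTable
from .types import BUCKETS, CONDITIONS

_AGE_BOUNDS = {"18-44": (18, 44), "45-64": (45, 64), "65-74": (65, 74), "75-85": (75, 85)}

# Published overall marginals of the emulated population.
AGE_MARGINAL = {"18-44": 0.342, "45-64": 0.395, "65-74": 0.169, "75-85": 0.094}
SEX_MARGINAL = {"female": 0.573, "male": 0.427}
RACE_MARGINAL = {"nh_white": 0.739, "nh_black": 0.071, "hispanic": 0.034,
                 "other": 0.105, "missing": 0.051}

# Age-graded true prevalences (package defaults; realistic U.S. primary-care
# gradients chosen so population totals land near the emulated study's
# richest-evidence estimates).
_HTN_BY_AGE = {"18-44": 0.15, "45-64": 0.42, "65-74": 0.62, "75-85": 0.72}
_HTN_BLACK_EXTRA = 0.06
_OBESITY_BY_AGE = {"18-44": 0.38, "45-64": 0.49, "65-74": 0.47, "75-85": 0.38}
_DIABETES_BY_AGE = {"18-44": 0.07, "45-64": 0.18, "65-74": 0.28, "75-85": 0.30}
_CKD_BY_AGE = {"18-44": 0.01, "45-64": 0.05, "65-74": 0.15, "75-85": 0.30}


def default_demographic_mix() -> dict[tuple, float]:
    """Joint sex x race/ethnicity x age-group mix as a product of marginals."""
    mix = {}
    for sex, race, band in itertools.product(SEXES, RACE_ETHNICITIES, AGE_GROUPS):
        mix[(sex, race, band)] = SEX_MARGINAL[sex] * RACE_MARGINAL[race] * AGE_MARGINAL[band]
    return mix


def prevalence_by_age(by_age: Mapping[str, float], black_extra: float = 0.0,
                      cap: float = 0.95) -> dict[tuple, float]:
    """Expand an age-graded prevalence into a full known-race stratum map."""
    out = {}
    for sex, race, band in itertools.product(SEXES, KNOWN_RACES, AGE_GROUPS):
        p = by_age[band] + (black_extra if race == "nh_black" else 0.0)
        out[(sex, race, band)] = min(p, cap)
    return out


def default_true_htn_prevalence() -> dict[tuple, float]:
    return prevalence_by_age(_HTN_BY_AGE, black_extra=_HTN_BLACK_EXTRA)


def default_comorbidity_prevalence() -> dict[tuple, float]:
    maps = {"obesity": _OBESITY_BY_AGE, "diabetes": _DIABETES_BY_AGE, "ckd": _CKD_BY_AGE}
    out = {}
    for cond, by_age in maps.items():
        for key, p in prevalence_by_age(by_age).items():
            out[(cond, key)] = p
    return out


def uniform_prevalence(p: float) -> dict[tuple, float]:
    return {key: p for key in DEMO_KEYS}


def uniform_comorbidity_prevalence(p_obesity: float, p_diabetes: float,
                                   p_ckd: float) -> dict[tuple, float]:
    out = {}
    for cond, p in (("obesity", p_obesity), ("diabetes", p_diabetes), ("ckd", p_ckd)):
        for key in DEMO_KEYS:
            out[(cond, key)] = p
    return out


@dataclass(frozen=True)
class BpModel:
    """Visit-level office-BP generative model (means and noise SD, mm Hg)."""
    hypertensive_mean: tuple[float, float] = (150.0, 92.0)
    normotensive_mean: tuple[float, float] = (118.0, 74.0)
    noise_sd: tuple[float, float] = (12.0, 8.0)


@dataclass
class SimulationParams:
    """All knobs of the synthetic cohort; defaults are the emulated study conditions."""

    n_patients: int = 10_000
    org_count: int = 5
    observation_year: int = 2016
    demographic_mix: dict = field(default_factory=default_demographic_mix)
    true_htn_prevalence: dict = field(default_factory=default_true_htn_prevalence)
    comorbidity_prevalence: dict = field(default_factory=default_comorbidity_prevalence)
    # P(billing-claim code in-year | true case), per condition.
    claims_sensitivity: dict = field(default_factory=lambda: {
        "hypertension": 0.74, "obesity": 0.24, "diabetes": 0.69, "ckd": 0.46})
    # P(problem-list code | true case without a claim), per condition.
    problem_list_increment: dict = field(default_factory=lambda: {
        "hypertension": 0.09, "obesity": 0.07, "diabetes": 0.31, "ckd": 0.25})
    # P(clinical criterion evidence recorded), per comorbidity.
    clinical_documentation_rate: dict = field(default_factory=lambda: {
        "obesity": 0.93, "diabetes": 0.75, "ckd": 0.60})
    visit_count_distribution: dict = field(default_factory=lambda: {
        1: 0.25, 2: 0.25, 3: 0.20, 4: 0.15, 5: 0.10, 6: 0.05})
    bp_missingness: float = 0.059
    bp_model: BpModel = field(default_factory=BpModel)
    # Per-organization multiplicative tilt on claims/problem-list documentation,
    # drawn uniformly from this range — produces cross-org spread in observed
    # prevalence like real billing-practice variation.
    org_tilt_range: tuple[float, float] = (0.85, 1.10)
    # Effective survey size behind each reference-table stratum estimate.
    pseudo_survey_size: int = 5_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.org_count < 1:
            raise ValueError("org_count must be >= 1")
        for name, dist in (("demographic_mix", self.demographic_mix),
                           ("visit_count_distribution", self.visit_count_distribution)):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(v < 0 for v in dist.values()):
                raise ValueError(f"{name} has negative entries")
        fracs = (list(self.true_htn_prevalence.values())
                 + list(self.comorbidity_prevalence.values())
                 + list(self.claims_sensitivity.values())
                 + list(self.problem_list_increment.values())
                 + list(self.clinical_documentation_rate.values())
                 + [self.bp_missingness])
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for key in DEMO_KEYS:
            if key not in self.true_htn_prevalence:
                raise ValueError(f"true_htn_prevalence missing stratum {key}")
            for cond in CONDITIONS:
                if (cond, key) not in self.comorbidity_prevalence:
                    raise ValueError(f"comorbidity_prevalence missing ({cond}, {key})")


def _conditional_known_race(mix: Mapping[tuple, float]) -> dict[tuple, tuple[list, np.ndarray]]:
    """Per (sex, age-group): known races and their conditional probabilities."""
    out = {}
    for sex in SEXES:
        for band in AGE_GROUPS:
            races, probs = [], []
            for race in KNOWN_RACES:
                w = mix.get((sex, race, band), 0.0)
                if w > 0:
                    races.append(race)
                    probs.append(w)
            if not races:
                races = list(KNOWN_RACES)
                probs = [1.0] * len(races)
            p = np.asarray(probs, dtype=float)
            out[(sex, band)] = (races, p / p.sum())
    return out


def _org_tilts(params: SimulationParams) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x0B5E]))
    lo, hi = params.org_tilt_range
    return rng.uniform(lo, hi, size=params.org_count)


def _day(year: int, ordinal: int) -> pd.Timestamp:
    return pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=int(ordinal))


def generate_cohort(params: SimulationParams) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort and its ground truth; deterministic given the seed.

    Ground-truth columns: patient_id, org_id, sex, race_ethnicity (the
    latent known race, even when the recorded one is missing), age_group,
    true_htn, true_obesity, true_diabetes, true_ckd.
    """
    params.validate()
    year = params.observation_year
    n_days = 365 + int(pd.Timestamp(f"{year}-12-31").dayofyear == 366)

    mix_keys = list(params.demographic_mix.keys())
    mix_probs = np.asarray(list(params.demographic_mix.values()), dtype=float)
    mix_probs = mix_probs / mix_probs.sum()
    mix_cum = np.cumsum(mix_probs)
    cond_race = _conditional_known_race(params.demographic_mix)
    tilts = _org_tilts(params)
    visit_ks = np.asarray(list(params.visit_count_distribution.keys()))
    visit_cum = np.cumsum(np.asarray(list(params.visit_count_distribution.values())))
    bm = params.bp_model

    patients, encounters, diagnoses, bp_rows, meas_rows, truth = [], [], [], [], [], []

    for i in range(params.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, i]))
        pid = f"p{i:07d}"
        sex, race_obs, band = mix_keys[int(np.searchsorted(mix_cum, rng.random(), side="left"))]
        if race_obs == "missing":
            races, probs = cond_race[(sex, band)]
            race_true = races[int(np.searchsorted(np.cumsum(probs), rng.random()))]
        else:
            race_true = race_obs
        lo, hi = _AGE_BOUNDS[band]
        age = int(rng.integers(lo, hi + 1))
        org_idx = int(rng.integers(params.org_count))
        org = f"org{org_idx + 1:02d}"
        tilt = tilts[org_idx]
        stratum = (sex, race_true, band)

        true_htn = rng.random() < params.true_htn_prevalence[stratum]
        true_cond = {c: rng.random() < params.comorbidity_prevalence[(c, stratum)]
                     for c in CONDITIONS}

        patients.append((pid, org, sex, age, race_obs))
        truth.append((pid, org, sex, race_true, band, true_htn,
                      true_cond["obesity"], true_cond["diabetes"], true_cond["ckd"]))

        # Visits: first is always ambulatory E&M (eligibility anchor).
        k = int(visit_ks[int(np.searchsorted(visit_cum, rng.random()))])
        visit_days = np.sort(rng.choice(n_days, size=min(k, n_days), replace=False))
        for j, day in enumerate(visit_days):
            setting = "ambulatory_em" if (j == 0 or rng.random() < 0.9) else "other"
            encounters.append((pid, _day(year, day), setting))

        def clip01(x: float) -> float:
            return min(max(x, 0.0), 1.0)

        def document(condition: str, codes: tuple[str, str]) -> None:
            claim_code, pl_code = codes
            day = int(rng.integers(n_days))
            if rng.random() < clip01(params.claims_sensitivity[condition] * tilt):
                diagnoses.append((pid, _day(year, day), claim_code, "claim"))
            elif rng.random() < clip01(params.problem_list_increment[condition] * tilt):
                diagnoses.append((pid, _day(year, day), pl_code, "problem_list"))

        if true_htn:
            document("hypertension", ("I10", "I10"))
        if true_cond["obesity"]:
            document("obesity", ("E66.9", "E66.9"))
        if true_cond["diabetes"]:
            document("diabetes", ("E11.9", "E11.9"))
        if true_cond["ckd"]:
            document("ckd", ("N18.3", "N18.3"))

        # Clinical measurements: qualifying values for documented true cases,
        # unremarkable values (same recording rate) otherwise.
        rate = params.clinical_documentation_rate
        if rng.random() < rate["obesity"]:
            bmi = (max(30.1, rng.normal(34.0, 3.0)) if true_cond["obesity"]
                   else min(29.5, max(16.0, rng.normal(26.0, 2.5))))
            meas_rows.append((pid, _day(year, int(rng.integers(n_days))), "bmi", round(bmi, 1)))
        if rng.random() < rate["diabetes"]:
            a1c = (max(6.5, rng.normal(7.5, 1.0)) if true_cond["diabetes"]
                   else min(6.4, max(4.0, rng.normal(5.5, 0.3))))
            meas_rows.append((pid, _day(year, int(rng.integers(n_days))), "hba1c", round(a1c, 1)))
        if rng.random() < rate["ckd"]:
            if true_cond["ckd"]:
                d1 = int(rng.integers(0, n_days - 120))
                d2 = d1 + 90 + int(rng.integers(0, 30))
                for d in (d1, d2):
                    egfr = min(59.0, max(10.0, rng.normal(45.0, 8.0)))
                    meas_rows.append((pid, _day(year, d), "egfr", round(egfr, 1)))
            else:
                egfr = max(61.0, rng.normal(85.0, 10.0))
                meas_rows.append((pid, _day(year, int(rng.integers(n_days))), "egfr",
                                  round(egfr, 1)))

        # Office BP: one reading per visit unless the patient is never measured.
        if rng.random() >= params.bp_missingness:
            mean_s, mean_d = bm.hypertensive_mean if true_htn else bm.normotensive_mean
            for day in visit_days:
                s = int(round(rng.normal(mean_s, bm.noise_sd[0])))
                d = int(round(rng.normal(mean_d, bm.noise_sd[1])))
                s = min(max(s, 70), 250)
                d = min(max(d, 40), 160)
                if d >= s:
                    d = s - 10
                bp_rows.append((pid, _day(year, day), s, d))

    cohort = Cohort(
        patients=pd.DataFrame(patients, columns=["patient_id", "org_id", "sex", "age",
                                                 "race_ethnicity"]),
        encounters=pd.DataFrame(encounters, columns=["patient_id", "date", "setting"]),
        diagnoses=pd.DataFrame(diagnoses, columns=["patient_id", "date", "code", "source"]),
        bp_readings=pd.DataFrame(bp_rows, columns=["patient_id", "date", "systolic",
                                                   "diastolic"]),
        measurements=pd.DataFrame(meas_rows, columns=["patient_id", "date", "kind", "value"]),
        observation_year=year,
    )
    ground_truth = pd.DataFrame(truth, columns=[
        "patient_id", "org_id", "sex", "race_ethnicity", "age_group",
        "true_htn", "true_obesity", "true_diabetes", "true_ckd"])
    return cohort, ground_truth


def bucket_distribution_from_params(params: SimulationParams, stratum: tuple) -> dict[str, float]:
    """Closed-form count-bucket shares implied by independent conditions."""
    ps = [params.comorbidity_prevalence[(c, stratum)] for c in CONDITIONS]
    p0 = math.prod(1.0 - p for p in ps)
    p1 = sum(p * math.prod(1.0 - q for j, q in enumerate(ps) if j != i)
             for i, p in enumerate(ps))
    return {"zero": p0, "one": p1, "two_or_three": 1.0 - p0 - p1}


def generate_reference_table(params: SimulationParams) -> ReferenceTable:
    """The reference table implied by the generator's own truth.

    True hypertension status is independent of the comorbidity count given
    the demographic stratum, so in joint mode every bucket inherits the
    stratum prevalence. Standard errors are binomial on the configured
    pseudo-survey size per stratum.
    """
    params.validate()
    n_s = params.pseudo_survey_size
    rows, dist_rows = [], []
    for key in DEMO_KEYS:
        s, r, a = key
        p = params.true_htn_prevalence[key]
        se = math.sqrt(p * (1.0 - p) / n_s)
        q = bucket_distribution_from_params(params, key)
        for b in BUCKETS:
            rows.append({"sex": s, "race_ethnicity": r, "age_group": a,
                         "count_bucket": b, "prevalence": p, "se": se})
            dist_rows.append({"sex": s, "race_ethnicity": r, "age_group": a,
                              "count_bucket": b, "share": q[b]})
    return ReferenceTable(strata=pd.DataFrame(rows),
                          bucket_distributions=pd.DataFrame(dist_rows))
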