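from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from htngap import ascertain as A
from htngap.codesets import CodeSets, DEFAULT_CODE_SETS
from htngap.cohort import Cohort, eligible_patients
from htngap.simulate import SimulationParams, generate_cohort, uniform_prevalence
from htngap.types import LEVELS

from oracles import flags_oracle, random_raw_cohort, tier_oracle

D = pd.Timestamp


def _dx(rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "code", "source"])


def _meas(rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "kind", "value"])


class TestBpCriteria:
    @pytest.mark.parametrize("readings,expected", [
        ([(D("2016-01-05"), 165, 88)], True),                       # single-reading arm
        ([(D("2016-01-05"), 144, 92), (D("2016-02-04"), 141, 85)], True),  # two days
        ([(D("2016-01-05"), 144, 92), (D("2016-01-05"), 150, 95)], False),  # same day
        ([], False),
        ([(D("2016-03-01"), 150, 95), (D("2016-03-09"), 142, 90)], True),
        ([(D("2016-03-01"), 139, 89)], False),
        ([(D("2016-03-01"), 120, 100)], True),                      # diastolic arm
    ])
    def test_rule(self, readings, expected):
        assert A.bp_criteria_met(readings) is expected

    def test_and_mode_requires_both_components(self):
        cs = DEFAULT_CODE_SETS.with_overrides(bp_require_both=True)
        assert A.bp_criteria_met([(D("2016-01-05"), 165, 88)], cs) is False
        assert A.bp_criteria_met([(D("2016-01-05"), 165, 101)], cs) is True


class TestHypertensionTier:
    def test_claims_beats_problem_list(self):
        dx = _dx([("x", D("2016-01-01"), "I10", "claim"),
                  ("x", D("2016-02-01"), "I10", "problem_list")])
        assert A.hypertension_tier(dx, []) == "claims"

    def test_problem_list_only(self):
        dx = _dx([("x", D("2016-01-01"), "I10", "problem_list")])
        assert A.hypertension_tier(dx, []) == "problem_list"

    def test_bp_fallback(self):
        readings = [(D("2016-01-01"), 150, 95), (D("2016-01-08"), 142, 90)]
        assert A.hypertension_tier(_dx([]), readings) == "bp_criteria"

    def test_non_hypertension_code_is_none(self):
        dx = _dx([("x", D("2016-01-01"), "E66.9", "claim")])
        assert A.hypertension_tier(dx, []) == "none"

    def test_prefix_matching_is_undotted(self):
        dx = _dx([("x", D("2016-01-01"), "I11.0", "claim")])
        assert A.hypertension_tier(dx, []) == "claims"


class TestConditionFlags:
    def test_bmi_only_is_clinical_level(self):
        flags = A.condition_flags(_dx([]), _meas([("x", D("2016-05-01"), "bmi", 31.2)]))
        assert flags["obesity"] == "plus_clinical"

    def test_claim_code_wins(self):
        flags = A.condition_flags(_dx([("x", D("2016-01-01"), "E66.9", "claim")]),
                                  _meas([("x", D("2016-05-01"), "bmi", 31.2)]))
        assert flags["obesity"] == "claims_only"

    def test_single_low_egfr_insufficient(self):
        flags = A.condition_flags(_dx([]), _meas([("x", D("2016-05-01"), "egfr", 45.0)]))
        assert flags["ckd"] == "none"

    def test_two_low_egfr_far_apart_qualify(self):
        flags = A.condition_flags(_dx([]), _meas([
            ("x", D("2016-01-10"), "egfr", 45.0), ("x", D("2016-06-01"), "egfr", 52.0)]))
        assert flags["ckd"] == "plus_clinical"

    def test_two_low_egfr_too_close_do_not_qualify(self):
        flags = A.condition_flags(_dx([]), _meas([
            ("x", D("2016-01-10"), "egfr", 45.0), ("x", D("2016-02-01"), "egfr", 52.0)]))
        assert flags["ckd"] == "none"

    def test_glucose_needs_two_distinct_dates(self):
        one = A.condition_flags(_dx([]), _meas([
            ("x", D("2016-01-10"), "fasting_glucose", 130.0),
            ("x", D("2016-01-10"), "fasting_glucose", 140.0)]))
        assert one["diabetes"] == "none"
        two = A.condition_flags(_dx([]), _meas([
            ("x", D("2016-01-10"), "fasting_glucose", 130.0),
            ("x", D("2016-02-10"), "fasting_glucose", 140.0)]))
        assert two["diabetes"] == "plus_clinical"

    def test_hba1c_alone_qualifies(self):
        flags = A.condition_flags(_dx([]), _meas([("x", D("2016-03-01"), "hba1c", 6.7)]))
        assert flags["diabetes"] == "plus_clinical"


def _four_tier_cohort() -> Cohort:
    c = Cohort.empty(2016)
    c.patients = pd.DataFrame(
        [("a", "o", "female", 50, "nh_white"), ("b", "o", "male", 50, "nh_white"),
         ("c", "o", "female", 50, "nh_white"), ("d", "o", "male", 50, "nh_white")],
        columns=["patient_id", "org_id", "sex", "age", "race_ethnicity"])
    c.encounters = pd.DataFrame(
        [(p, D("2016-06-01"), "ambulatory_em") for p in "abcd"],
        columns=["patient_id", "date", "setting"])
    c.diagnoses = _dx([("a", D("2016-01-01"), "I10", "claim"),
                       ("b", D("2016-01-01"), "I10", "problem_list")])
    c.bp_readings = pd.DataFrame(
        [("c", D("2016-01-01"), 150, 95), ("c", D("2016-01-09"), 145, 92),
         ("d", D("2016-01-01"), 120, 80)],
        columns=["patient_id", "date", "systolic", "diastolic"])
    return c


class TestObservedPrevalence:
    def test_enumeration_across_levels(self):
        c = _four_tier_cohort()
        elig = {"a", "b", "c", "d"}
        values = [A.observed_prevalence(c, elig, lev).pct for lev in LEVELS]
        assert values == [25.0, 50.0, 75.0]

    def test_all_none_is_zero(self):
        c = _four_tier_cohort()
        c.diagnoses = _dx([])
        c.bp_readings = c.bp_readings.iloc[0:0]
        for lev in LEVELS:
            assert A.observed_prevalence(c, {"a", "b", "c", "d"}, lev).value == 0.0

    def test_claims_level_recovers_sensitivity_times_prevalence(self):
        # s = 0.85, uniform p = 0.35 -> claims-level observed ~ 0.2975.
        params = SimulationParams(
            n_patients=20_000, seed=3, org_tilt_range=(1.0, 1.0),
            true_htn_prevalence=uniform_prevalence(0.35),
            claims_sensitivity={"hypertension": 0.85, "obesity": 0.24,
                                "diabetes": 0.69, "ckd": 0.46})
        cohort, _ = generate_cohort(params)
        elig = eligible_patients(cohort)
        obs = A.observed_prevalence(cohort, elig, "claims_only")
        se = math.sqrt(0.2975 * (1 - 0.2975) / 20_000)
        assert abs(obs.value - 0.2975) < 3 * se

    def test_empty_eligible_rejected(self):
        with pytest.raises(ValueError):
            A.observed_prevalence(_four_tier_cohort(), set(), "claims_only")


class TestComorbidityDistribution:
    def test_enumeration(self):
        c = _four_tier_cohort()
        c.diagnoses = _dx([("a", D("2016-01-01"), "E66.9", "claim"),
                           ("b", D("2016-01-01"), "E66.9", "claim"),
                           ("b", D("2016-01-02"), "E11.9", "claim")])
        dist = A.comorbidity_distribution(c, {"a", "b", "c"}, "claims_only")
        assert dist["buckets"] == pytest.approx(
            {"zero": 1 / 3, "one": 1 / 3, "two_or_three": 1 / 3})

    def test_no_conditions_degenerate(self):
        c = _four_tier_cohort()
        c.diagnoses = _dx([])
        dist = A.comorbidity_distribution(c, {"a", "b", "c", "d"}, "plus_clinical")
        assert dist["buckets"] == {"zero": 1.0, "one": 0.0, "two_or_three": 0.0}

    def test_bucket_and_condition_monotonicity_across_levels(self):
        cohort, _ = generate_cohort(SimulationParams(n_patients=5000, seed=3))
        elig = eligible_patients(cohort)
        asc = A.ascertain(cohort, elig, DEFAULT_CODE_SETS)
        dists = [A.comorbidity_distribution(cohort, elig, lev, ascertainment=asc)
                 for lev in LEVELS]
        for cond in ("obesity", "diabetes", "ckd"):
            prev = [d["conditions"][cond] for d in dists]
            assert prev == sorted(prev)
        two3 = [d["buckets"]["two_or_three"] for d in dists]
        assert two3 == sorted(two3)
        for d in dists:
            assert sum(d["buckets"].values()) == pytest.approx(1.0)


class TestProperties:
    def test_tier_exclusivity_counts_sum(self):
        cohort, _ = generate_cohort(SimulationParams(n_patients=2000, seed=9))
        elig = eligible_patients(cohort)
        asc = A.ascertain(cohort, elig, DEFAULT_CODE_SETS)
        assert asc["htn_tier"].isin(("claims", "problem_list", "bp_criteria", "none")).all()
        assert len(asc) == len(elig)

    def test_observed_prevalence_monotone_in_level(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            cohort = random_raw_cohort(rng, n_max=120)
            elig = eligible_patients(cohort)
            if not elig:
                continue
            asc = A.ascertain(cohort, elig, DEFAULT_CODE_SETS)
            vals = [A.observed_prevalence(cohort, elig, lev, ascertainment=asc).value
                    for lev in LEVELS]
            assert vals == sorted(vals)

    def test_vectorized_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12345)
        cs = DEFAULT_CODE_SETS
        for _ in range(8):
            cohort = random_raw_cohort(rng, n_max=150)
            elig = eligible_patients(cohort)
            if not elig:
                continue
            asc = A.ascertain(cohort, elig, cs).set_index("patient_id")
            for pid in elig:
                dx_rows = [(r.date, r.code, r.source)
                           for r in cohort.diagnoses.itertuples() if r.patient_id == pid]
                bp_rows = [(r.date, r.systolic, r.diastolic)
                           for r in cohort.bp_readings.itertuples() if r.patient_id == pid]
                meas_rows = [(r.date, r.kind, r.value)
                             for r in cohort.measurements.itertuples() if r.patient_id == pid]
                assert asc.loc[pid, "htn_tier"] == tier_oracle(
                    dx_rows, bp_rows, 2016, cs)
                expected_flags = flags_oracle(dx_rows, meas_rows, 2016, cs)
                for cond, lev in expected_flags.items():
                    assert asc.loc[pid, f"{cond}_level"] == lev


class TestBpScreeningGap:
    def test_counting(self):
        c = _four_tier_cohort()
        # d has a reading; drop c's readings so a, b, c lack them.
        c.bp_readings = c.bp_readings[c.bp_readings.patient_id == "d"]
        gap, per_org = A.bp_screening_gap(c, {"a", "b", "c", "d"})
        assert gap == 0.75
        assert per_org["o"] == 0.75

    def test_all_have_readings(self):
        c = _four_tier_cohort()
        extra = pd.DataFrame([(p, D("2016-06-01"), 120, 80) for p in "ab"],
                             columns=["patient_id", "date", "systolic", "diastolic"])
        c.bp_readings = pd.concat([c.bp_readings, extra], ignore_index=True)
        gap, _ = A.bp_screening_gap(c, {"a", "b", "c", "d"})
        assert gap == 0.0
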