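from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from htngap import estimator as E
from htngap.cohort import Cohort, eligible_patients
from htngap.simulate import (SimulationParams, generate_cohort, generate_reference_table,
                             uniform_comorbidity_prevalence)

from oracles import expectation_oracle

K1 = ("female", "nh_white", "18-44")
K2 = ("male", "nh_black", "45-64")


def _table_with(pmap: dict, se: float = 0.0) -> E.ReferenceTable:
    base = E.uniform_reference_table(0.0, se)
    strata = base.strata.copy()
    for key, p in pmap.items():
        mask = ((strata.sex == key[0]) & (strata.race_ethnicity == key[1])
                & (strata.age_group == key[2]))
        strata.loc[mask, "prevalence"] = p
    return E.ReferenceTable(strata=strata)


class TestPredictedPrevalence:
    def test_linearity(self):
        table = _table_with({K1: 0.20, K2: 0.40})
        est = E.predicted_prevalence({K1: 0.5, K2: 0.5}, table, n=100)
        assert est.value == pytest.approx(0.30, abs=1e-15)
        assert (est.ci_low, est.ci_high) == (est.value, est.value)

    def test_single_stratum_identity(self):
        table = _table_with({K1: 0.335})
        est = E.predicted_prevalence({K1: 1.0}, table, n=10)
        assert est.value == pytest.approx(0.335, abs=1e-15)

    def test_matches_patient_level_expectation_oracle(self):
        rng = np.random.default_rng(21)
        keys = list(E.DEMO_KEYS[:6])
        pmap = {k: float(rng.uniform(0.1, 0.6)) for k in keys}
        table = _table_with(pmap)
        # Synthetic patient list over the 6 strata.
        patients = [keys[int(rng.integers(6))] for _ in range(500)]
        weights = {k: patients.count(k) / len(patients) for k in keys if patients.count(k)}
        est = E.predicted_prevalence(weights, table, n=len(patients))
        assert est.value == pytest.approx(expectation_oracle(patients, pmap), abs=1e-12)

    def test_se_propagation(self):
        table = _table_with({K1: 0.2, K2: 0.4}, se=0.0)
        strata = table.strata.copy()
        strata.loc[:, "se"] = 0.02
        table = E.ReferenceTable(strata=strata)
        est = E.predicted_prevalence({K1: 0.5, K2: 0.5}, table, n=100)
        expected_se = math.sqrt(2 * (0.5 * 0.02) ** 2)
        assert est.ci_high - est.value == pytest.approx(1.959963984540054 * expected_se,
                                                        abs=1e-12)

    def test_missing_stratum_rejected(self):
        table = E.uniform_reference_table(0.2, joint=True)
        with pytest.raises(KeyError):
            E.predicted_prevalence({K1 + ("four",): 1.0}, table, n=10)

    def test_mode_mismatch_rejected(self):
        table = _table_with({K1: 0.2})
        with pytest.raises(ValueError, match="mode mismatch"):
            E.predicted_prevalence({K1 + ("zero",): 1.0}, table, n=10)

    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=8),
           st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8))
    def test_bounded_by_stratum_range(self, pis, raw_w):
        k = min(len(pis), len(raw_w))
        pis, raw_w = pis[:k], raw_w[:k]
        keys = list(E.DEMO_KEYS[:k])
        total = sum(raw_w)
        weights = {key: w / total for key, w in zip(keys, raw_w)}
        table = _table_with(dict(zip(keys, pis)))
        est = E.predicted_prevalence(weights, table, n=100)
        assert min(pis) - 1e-12 <= est.value <= max(pis) + 1e-12

    def test_self_consistency_with_reference_composition(self):
        # Weights equal to the reference population's own composition return
        # the reference overall prevalence exactly.
        rng = np.random.default_rng(5)
        pmap = {k: float(rng.uniform(0.05, 0.8)) for k in E.DEMO_KEYS}
        comp = rng.dirichlet(np.ones(len(E.DEMO_KEYS)))
        weights = dict(zip(E.DEMO_KEYS, comp))
        overall = float(sum(comp[i] * pmap[k] for i, k in enumerate(E.DEMO_KEYS)))
        est = E.predicted_prevalence(weights, _table_with(pmap), n=1000)
        assert est.value == pytest.approx(overall, abs=1e-12)

    def test_wald_ci_method(self):
        table = _table_with({K1: 0.335})
        est = E.predicted_prevalence({K1: 1.0}, table, n=400, ci_method="wald")
        se = math.sqrt(0.335 * 0.665 / 400)
        assert est.ci_high == pytest.approx(0.335 + 1.959963984540054 * se, abs=1e-12)


def _cohort_from_patients(rows) -> Cohort:
    c = Cohort.empty(2016)
    c.patients = pd.DataFrame(rows, columns=["patient_id", "org_id", "sex", "age",
                                             "race_ethnicity"])
    c.encounters = pd.DataFrame(
        [(r[0], pd.Timestamp("2016-06-01"), "ambulatory_em") for r in rows],
        columns=["patient_id", "date", "setting"])
    return c


class TestStratumWeights:
    def test_degenerate_single_stratum(self):
        c = _cohort_from_patients([(f"p{i}", "o", "female", 30, "nh_white")
                                   for i in range(4)])
        w = E.stratum_weights(c, {f"p{i}" for i in range(4)})
        assert w == {("female", "nh_white", "18-44"): 1.0}

    def test_two_patients_split_by_sex(self):
        c = _cohort_from_patients([("a", "o", "female", 30, "nh_white"),
                                   ("b", "o", "male", 30, "nh_white")])
        w = E.stratum_weights(c, {"a", "b"})
        assert w[("female", "nh_white", "18-44")] == pytest.approx(0.5)
        assert w[("male", "nh_white", "18-44")] == pytest.approx(0.5)

    def test_missing_race_redistributed_proportionally(self):
        # 90 known-race (60 white, 30 black) + 10 missing, all same sex x age:
        # missing mass splits 2:1; known-race proportions preserved.
        rows = ([(f"w{i}", "o", "female", 30, "nh_white") for i in range(60)]
                + [(f"b{i}", "o", "female", 30, "nh_black") for i in range(30)]
                + [(f"m{i}", "o", "female", 30, "missing") for i in range(10)])
        c = _cohort_from_patients(rows)
        w = E.stratum_weights(c, {r[0] for r in rows})
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
        white = w[("female", "nh_white", "18-44")]
        black = w[("female", "nh_black", "18-44")]
        assert white == pytest.approx((60 + 10 * (60 / 90)) / 100, abs=1e-12)
        assert black == pytest.approx((30 + 10 * (30 / 90)) / 100, abs=1e-12)
        assert white / black == pytest.approx(2.0, abs=1e-9)

    def test_weights_sum_to_one_on_generated_cohort(self):
        cohort, _ = generate_cohort(SimulationParams(n_patients=2000, seed=13))
        w = E.stratum_weights(cohort, eligible_patients(cohort))
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in w.values())
        assert all(k[1] != "missing" for k in w)


class TestFoldReferenceComorbidity:
    def _joint_table(self, bucket_ps, shares) -> E.ReferenceTable:
        base = E.uniform_reference_table(0.0, joint=True)
        strata = base.strata.copy()
        for bucket, p in bucket_ps.items():
            strata.loc[strata.count_bucket == bucket, "prevalence"] = p
        dist = base.bucket_distributions.copy()
        for bucket, q in shares.items():
            dist.loc[dist.count_bucket == bucket, "share"] = q
        return E.ReferenceTable(strata=strata, bucket_distributions=dist)

    def test_weighted_mean_example(self):
        table = self._joint_table({"zero": 0.2, "one": 0.4, "two_or_three": 0.6},
                                  {"zero": 0.5, "one": 0.3, "two_or_three": 0.2})
        folded = E.fold_reference_comorbidity(table)
        assert np.allclose(folded.strata["prevalence"], 0.34)
        assert folded.mode == "demographic"

    def test_uniform_prevalence_unchanged(self):
        table = self._joint_table({"zero": 0.33, "one": 0.33, "two_or_three": 0.33},
                                  {"zero": 0.5, "one": 0.3, "two_or_three": 0.2})
        folded = E.fold_reference_comorbidity(table)
        assert np.allclose(folded.strata["prevalence"], 0.33)

    def test_fold_then_predict_equals_joint_prediction(self):
        rng = np.random.default_rng(17)
        params = SimulationParams(n_patients=10, seed=1)
        table = generate_reference_table(params)
        # Perturb prevalences across buckets so folding is non-trivial.
        strata = table.strata.copy()
        strata["prevalence"] = rng.uniform(0.1, 0.6, size=len(strata))
        table = E.ReferenceTable(strata=strata,
                                 bucket_distributions=table.bucket_distributions)
        demo_w = dict(zip(E.DEMO_KEYS, rng.dirichlet(np.ones(len(E.DEMO_KEYS)))))
        dist = table.bucket_distributions.set_index(
            ["sex", "race_ethnicity", "age_group", "count_bucket"])["share"]
        joint_w = {demo + (b,): wd * float(dist[demo + (b,)])
                   for demo, wd in demo_w.items() for b in ("zero", "one", "two_or_three")}
        via_joint = E.predicted_prevalence(joint_w, table, n=100)
        via_fold = E.predicted_prevalence(demo_w, E.fold_reference_comorbidity(table),
                                          n=100)
        assert via_joint.value == pytest.approx(via_fold.value, abs=1e-12)
        assert via_joint.ci_high == pytest.approx(via_fold.ci_high, abs=1e-12)

    def test_demographic_table_cannot_fold(self):
        with pytest.raises(ValueError):
            E.fold_reference_comorbidity(E.uniform_reference_table(0.3))


class TestToolCompatibilityWeights:
    def test_product_example(self):
        demo = {K1: 0.6, K2: 0.4}
        bucket = {"zero": 0.5, "one": 0.5, "two_or_three": 0.0}
        w = E.tool_compatibility_weights(demo, bucket)
        assert len(w) == 6
        assert w[K1 + ("zero",)] == pytest.approx(0.30)

    def test_degenerate_bucket_marginal_preserves_demo_weights(self):
        demo = {K1: 0.6, K2: 0.4}
        w = E.tool_compatibility_weights(demo, {"zero": 1.0, "one": 0.0,
                                                "two_or_three": 0.0})
        assert w[K1 + ("zero",)] == pytest.approx(0.6)
        assert w[K2 + ("zero",)] == pytest.approx(0.4)

    def test_unnormalized_marginal_rejected(self):
        with pytest.raises(ValueError):
            E.tool_compatibility_weights({K1: 0.7}, {"zero": 1.0, "one": 0.0,
                                                     "two_or_three": 0.0})

    def test_joint_weights_near_product_under_independence(self):
        # Uniform comorbidity prevalence and documentation: the ascertained
        # bucket is independent of demographics, so patient-level joint
        # weights factor into the product of marginals (checked coarsely at
        # the sex x bucket margin, 3 MC SE).
        params = SimulationParams(
            n_patients=6000, seed=19, org_tilt_range=(1.0, 1.0),
            comorbidity_prevalence=uniform_comorbidity_prevalence(0.4, 0.15, 0.07))
        cohort, _ = generate_cohort(params)
        elig = eligible_patients(cohort)
        joint = E.stratum_weights(cohort, elig, level="plus_clinical",
                                  use_comorbidity=True)
        n = len(elig)
        sex_marg = {}
        bucket_marg = {}
        for (sex, _, _, bucket), w in joint.items():
            sex_marg[sex] = sex_marg.get(sex, 0.0) + w
            bucket_marg[bucket] = bucket_marg.get(bucket, 0.0) + w
        for sex, ws in sex_marg.items():
            for bucket, wb in bucket_marg.items():
                got = sum(w for k, w in joint.items()
                          if k[0] == sex and k[3] == bucket)
                expect = ws * wb
                se = math.sqrt(expect * (1 - expect) / n)
                assert abs(got - expect) < 3 * se + 1e-9


class TestReferenceTableIO:
    def test_round_trip(self, tmp_path):
        table = generate_reference_table(SimulationParams(n_patients=10, seed=2))
        table.write(tmp_path / "ref.csv", tmp_path / "buckets.csv")
        back = E.ReferenceTable.read(tmp_path / "ref.csv", tmp_path / "buckets.csv")
        pd.testing.assert_frame_equal(table.strata, back.strata, check_dtype=False)
        assert back.mode == "joint"

    def test_incomplete_table_rejected(self):
        table = E.uniform_reference_table(0.3)
        with pytest.raises(ValueError, match="incomplete"):
            E.ReferenceTable(strata=table.strata.iloc[:-1])

    def test_missing_file_named(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.csv"):
            E.ReferenceTable.read(tmp_path / "nope.csv")
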