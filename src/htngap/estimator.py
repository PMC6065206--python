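"""Expected hypertension prevalence by indirect standardization.

Given the composition of a patient population over strata (sex x
race/ethnicity x age group, optionally x comorbidity-count bucket) and a
reference table of stratum-specific prevalences pi_s with standard errors,
the predicted prevalence is the composition-weighted mean

    v = sum_s w_s * pi_s,      se(v) = sqrt(sum_s w_s^2 * se_s^2),

with a 95% CI v +/- 1.96*se clipped to [0, 1]. A Wald-on-N alternative
(se = sqrt(v(1-v)/n)) is selectable for populations without reference SEs.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import ascertain as asc_mod
from .codesets import CodeSets, DEFAULT_CODE_SETS
from .cohort import AGE_GROUPS, KNOWN_RACES, SEXES, Cohort, age_group
from .types import BUCKETS, CONDITIONS, LEVELS, PrevalenceEstimate, count_bucket

_Z95 = 1.959963984540054

#: Sentinel bucket value marking a demographic-only (no-comorbidity) row.
ALL_BUCKETS = "ALL"

DEMO_KEYS = tuple(itertools.product(SEXES, KNOWN_RACES, AGE_GROUPS))


def _demo_grid() -> pd.DataFrame:
    return pd.DataFrame(DEMO_KEYS, columns=["sex", "race_ethnicity", "age_group"])


@dataclass
class ReferenceTable:
    """Stratum-specific reference prevalences with standard errors.

    ``strata`` has columns sex, race_ethnicity, age_group, count_bucket,
    prevalence, se. In joint mode every demographic stratum appears once
    per comorbidity-count bucket; in demographic mode ``count_bucket`` is
    the sentinel ``"ALL"``. ``bucket_distributions`` (joint mode only)
    carries, per demographic stratum, the reference population's own
    count-bucket shares — used when an organization cannot supply its own
    comorbidity data.
    """

    strata: pd.DataFrame
    bucket_distributions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.strata = self.strata.reset_index(drop=True)
        self.validate()

    @property
    def mode(self) -> str:
        return "demographic" if (self.strata["count_bucket"] == ALL_BUCKETS).all() else "joint"

    def validate(self) -> None:
        req = ["sex", "race_ethnicity", "age_group", "count_bucket", "prevalence", "se"]
        missing = [c for c in req if c not in self.strata.columns]
        if missing:
            raise ValueError(f"reference table missing columns {missing}")
        bad = self.strata[(self.strata["prevalence"] < 0) | (self.strata["prevalence"] > 1)
                          | (self.strata["se"] < 0) | (self.strata["se"] > 1)]
        if len(bad):
            raise ValueError("reference prevalences and SEs must lie in [0, 1]")
        buckets = BUCKETS if self.mode == "joint" else (ALL_BUCKETS,)
        want = {(s, r, a, b) for (s, r, a) in DEMO_KEYS for b in buckets}
        have = set(map(tuple, self.strata[["sex", "race_ethnicity", "age_group",
                                           "count_bucket"]].itertuples(index=False)))
        if want - have:
            example = sorted(want - have)[0]
            raise ValueError(f"reference table incomplete: missing stratum {example} "
                             f"(+{len(want - have) - 1} more)")
        if self.bucket_distributions is not None:
            g = self.bucket_distributions.groupby(["sex", "race_ethnicity", "age_group"])["share"].sum()
            if not ((g - 1.0).abs() < 1e-9).all():
                raise ValueError("reference bucket distributions must sum to 1 per stratum")

    def prevalence_map(self) -> dict[tuple, tuple[float, float]]:
        out = {}
        for row in self.strata.itertuples(index=False):
            key = (row.sex, row.race_ethnicity, row.age_group)
            if self.mode == "joint":
                key = key + (row.count_bucket,)
            out[key] = (float(row.prevalence), float(row.se))
        return out

    def write(self, strata_path: str | Path, buckets_path: str | Path | None = None) -> None:
        self.strata.to_csv(strata_path, index=False)
        if self.bucket_distributions is not None and buckets_path is not None:
            self.bucket_distributions.to_csv(buckets_path, index=False)

    @classmethod
    def read(cls, strata_path: str | Path,
             buckets_path: str | Path | None = None) -> "ReferenceTable":
        strata_path = Path(strata_path)
        if not strata_path.exists():
            raise FileNotFoundError(f"reference table not found: {strata_path}")
        strata = pd.read_csv(strata_path)
        buckets = None
        if buckets_path is not None and Path(buckets_path).exists():
            buckets = pd.read_csv(buckets_path)
        return cls(strata=strata, bucket_distributions=buckets)


def uniform_reference_table(prevalence: float, se: float = 0.0,
                            joint: bool = False) -> ReferenceTable:
    """A complete reference table with one prevalence everywhere (mostly for tests)."""
    buckets = BUCKETS if joint else (ALL_BUCKETS,)
    rows = [{"sex": s, "race_ethnicity": r, "age_group": a, "count_bucket": b,
             "prevalence": prevalence, "se": se}
            for (s, r, a) in DEMO_KEYS for b in buckets]
    dist = None
    if joint:
        dist = pd.DataFrame([{"sex": s, "race_ethnicity": r, "age_group": a,
                              "count_bucket": b, "share": 1.0 / len(BUCKETS)}
                             for (s, r, a) in DEMO_KEYS for b in BUCKETS])
    return ReferenceTable(strata=pd.DataFrame(rows), bucket_distributions=dist)


def _patient_strata(cohort: Cohort, eligible: Iterable[str], level: str | None,
                    use_comorbidity: bool, code_sets: CodeSets,
                    ascertainment: pd.DataFrame | None) -> pd.DataFrame:
    pat = cohort.patients
    sub = pat[pat["patient_id"].isin(set(eligible))].copy()
    if not len(sub):
        raise ValueError("eligible set is empty")
    sub["age_group"] = sub["age"].astype(int).map(age_group)
    if use_comorbidity:
        if level is None:
            raise ValueError("an evidence level is required for comorbidity weighting")
        if ascertainment is None:
            ascertainment = asc_mod.ascertain(cohort, sub["patient_id"], code_sets)
        flags = pd.DataFrame({
            c: asc_mod.level_ascertained(ascertainment, c, level) for c in CONDITIONS})
        counts = flags.sum(axis=1).map(count_bucket)
        bucket_by_id = pd.Series(counts.values, index=ascertainment["patient_id"].values)
        sub["count_bucket"] = sub["patient_id"].map(bucket_by_id)
    return sub


def stratum_weights(cohort: Cohort, eligible: Iterable[str], level: str | None = None,
                    use_comorbidity: bool = False,
                    code_sets: CodeSets = DEFAULT_CODE_SETS,
                    ascertainment: pd.DataFrame | None = None) -> dict[tuple, float]:
    """Population composition over reference strata, from patient-level data.

    Keys are ``(sex, race_ethnicity, age_group)`` tuples, extended with the
    comorbidity-count bucket when ``use_comorbidity`` is set. Patients with
    missing race/ethnicity are redistributed proportionally over the known
    race categories observed within their sex x age-group cell (falling
    back to the cohort-wide known-race distribution, then to uniform, when
    a cell has no known-race patients). Weights are non-negative and sum
    to 1.
    """
    sub = _patient_strata(cohort, eligible, level, use_comorbidity, code_sets, ascertainment)
    n = len(sub)
    known = sub[sub["race_ethnicity"] != "missing"]
    missing = sub[sub["race_ethnicity"] == "missing"]

    weights: dict[tuple, float] = {}

    def add(key: tuple, w: float) -> None:
        weights[key] = weights.get(key, 0.0) + w

    key_cols = ["sex", "race_ethnicity", "age_group"]
    if use_comorbidity:
        key_cols.append("count_bucket")
    for row in known.itertuples(index=False):
        add(tuple(getattr(row, c) for c in key_cols), 1.0 / n)

    if len(missing):
        global_counts = known["race_ethnicity"].value_counts()
        cell_counts = known.groupby(["sex", "age_group"])["race_ethnicity"].value_counts()
        for row in missing.itertuples(index=False):
            cell = (row.sex, row.age_group)
            if cell in cell_counts.index.droplevel("race_ethnicity"):
                dist = cell_counts[cell]
            elif len(global_counts):
                dist = global_counts
            else:
                dist = pd.Series(1.0, index=list(KNOWN_RACES))
            dist = dist / dist.sum()
            for race, share in dist.items():
                key = [row.sex, race, row.age_group]
                if use_comorbidity:
                    key.append(row.count_bucket)
                add(tuple(key), share / n)

    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def predicted_prevalence(weights: Mapping[tuple, float], table: ReferenceTable,
                         n: int, ci_method: str = "reference_se") -> PrevalenceEstimate:
    """Composition-weighted expected prevalence with a 95% CI.

    ``ci_method`` is ``"reference_se"`` (propagate reference-table SEs in
    quadrature) or ``"wald"`` (binomial SE on the organization's own n).
    """
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("stratum weights must sum to 1")
    joint_weights = any(len(k) == 4 for k in weights)
    if joint_weights != (table.mode == "joint"):
        raise ValueError(
            f"mode mismatch: weights are {'joint' if joint_weights else 'demographic'} "
            f"but reference table is {table.mode}")
    pmap = table.prevalence_map()
    value = 0.0
    var = 0.0
    for key, w in weights.items():
        if key not in pmap:
            raise KeyError(f"stratum {key} absent from reference table")
        p, se = pmap[key]
        value += w * p
        var += (w * se) ** 2
    if ci_method == "reference_se":
        se_v = math.sqrt(var)
    elif ci_method == "wald":
        se_v = math.sqrt(max(value * (1.0 - value), 0.0) / n) if n else 0.0
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo = min(max(0.0, value - _Z95 * se_v), value)
    hi = max(min(1.0, value + _Z95 * se_v), value)
    return PrevalenceEstimate(value=value, ci_low=lo, ci_high=hi, n=n)


def fold_reference_comorbidity(table: ReferenceTable) -> ReferenceTable:
    """Collapse a joint-mode table to demographic-only mode.

    Each demographic stratum's prevalence becomes the mean over buckets
    weighted by the reference population's own bucket shares; SEs fold in
    quadrature with the same weights. Used when an organization supplies
    no comorbidity data of its own.
    """
    if table.mode != "joint":
        raise ValueError("fold_reference_comorbidity requires a joint-mode table")
    if table.bucket_distributions is None:
        raise ValueError("joint table has no reference bucket distributions to fold with")
    dist = table.bucket_distributions.set_index(
        ["sex", "race_ethnicity", "age_group", "count_bucket"])["share"]
    pmap = table.prevalence_map()
    rows = []
    for (s, r, a) in DEMO_KEYS:
        p = 0.0
        var = 0.0
        for b in BUCKETS:
            try:
                q = float(dist[(s, r, a, b)])
            except KeyError:
                raise ValueError(f"missing bucket distribution for stratum {(s, r, a, b)}")
            pb, seb = pmap[(s, r, a, b)]
            p += q * pb
            var += (q * seb) ** 2
        rows.append({"sex": s, "race_ethnicity": r, "age_group": a,
                     "count_bucket": ALL_BUCKETS, "prevalence": p, "se": math.sqrt(var)})
    return ReferenceTable(strata=pd.DataFrame(rows))


def tool_compatibility_weights(demographic_marginal: Mapping[tuple, float],
                               bucket_marginal: Mapping[str, float]) -> dict[tuple, float]:
    """Joint weights from summary marginals under independence.

    Emulates feeding the published estimator summary distributions (a
    demographic table and a comorbidity-count table) rather than
    patient-level data: the joint weight is the product of the marginals.
    """
    for name, marg in (("demographic", demographic_marginal), ("bucket", bucket_marginal)):
        if abs(sum(marg.values()) - 1.0) > 1e-9:
            raise ValueError(f"{name} marginal does not sum to 1")
    return {demo + (bucket,): wd * wb
            for demo, wd in demographic_marginal.items()
            for bucket, wb in bucket_marginal.items()}
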