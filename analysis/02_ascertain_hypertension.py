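"""Apply the nested case definitions and summarize what the data show.

Computes, for the simulated cohort: observed hypertension prevalence at
each evidence level (claims; claims or problem list; plus BP criteria),
the comorbidity prevalences and count-bucket distribution at each level,
the BP-screening gap, and the demographic composition. Writes
results/observed_prevalence.csv, results/comorbidity_distribution.csv,
results/bp_screening_gap.csv and results/demographics.csv.
"""
from __future__ import annotations

import pandas as pd

from htngap import ascertain as A
from htngap.codesets import DEFAULT_CODE_SETS
from htngap.cohort import eligible_patients, summarize_demographics
from htngap.types import LEVELS

from _common import RESULTS, ensure_cohort


def main() -> None:
    cohort, _ = ensure_cohort()
    elig = eligible_patients(cohort)
    print(f"eligible patients (18-85, ambulatory E&M visit in-year): {len(elig)}")

    asc = A.ascertain(cohort, elig, DEFAULT_CODE_SETS)
    tiers = asc["htn_tier"].value_counts()
    print("tier counts:", dict(tiers))

    rows = []
    for level in LEVELS:
        est = A.observed_prevalence(cohort, elig, level, ascertainment=asc)
        rows.append({"level": level, "observed_pct": est.pct, "n": est.n})
        print(f"observed prevalence at {level}: {est.pct:.1f}%")
    pd.DataFrame(rows).to_csv(RESULTS / "observed_prevalence.csv", index=False,
                              float_format="%.4f")

    crows = []
    for level in LEVELS:
        dist = A.comorbidity_distribution(cohort, elig, level, ascertainment=asc)
        for cond, p in dist["conditions"].items():
            crows.append({"level": level, "quantity": cond, "share": p})
        for bucket, p in dist["buckets"].items():
            crows.append({"level": level, "quantity": f"bucket_{bucket}", "share": p})
    pd.DataFrame(crows).to_csv(RESULTS / "comorbidity_distribution.csv", index=False,
                               float_format="%.4f")

    gap, per_org = A.bp_screening_gap(cohort, elig)
    print(f"BP-screening gap: {100 * gap:.1f}% of eligible patients have no BP reading "
          f"(org range {100 * per_org.min():.1f}-{100 * per_org.max():.1f}%)")
    out = pd.concat([pd.Series({"overall": gap}), per_org]).rename_axis("org_id")
    out.rename("no_bp_share").to_frame().to_csv(RESULTS / "bp_screening_gap.csv",
                                                float_format="%.4f")

    demo = summarize_demographics(cohort, elig)
    demo.to_csv(RESULTS / "demographics.csv", index=False, float_format="%.2f")
    overall = demo[(demo.org_id == "overall") & (demo.characteristic == "sex")]
    print("sex split:", {r.category: f"{r.pct:.1f}%" for r in overall.itertuples()})


if __name__ == "__main__":
    main()
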