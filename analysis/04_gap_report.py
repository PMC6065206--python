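"""Compare observed with predicted prevalence: the undiagnosed-hypertension gap.

Produces the headline table (observed vs predicted per evidence level,
percentage-point difference, additional patients, one-in-N ratio) overall
and per organization, plus cross-organization extrema. Writes
results/gap_by_level.md, results/gap_overall.csv and results/gap_by_org.csv.
"""
from __future__ import annotations

import pandas as pd

from htngap import gap as G
from htngap.cohort import eligible_patients
from htngap.pipeline import render_level_table
from htngap.types import LEVELS

from _common import RESULTS, ensure_cohort


def main() -> None:
    cohort, reference = ensure_cohort()
    elig = eligible_patients(cohort)

    overall = G.cohort_gaps(cohort, reference)
    overall_df = pd.DataFrame([r.to_row() for r in overall])
    overall_df.to_csv(RESULTS / "gap_overall.csv", index=False, float_format="%.4f")
    (RESULTS / "gap_by_level.md").write_text(render_level_table(overall_df, len(elig)))

    for r in overall:
        if r.comorbidity_mode != "org_comorbidity":
            continue
        ratio = f"one in {r.one_in_n}" if r.one_in_n else "no positive gap"
        print(f"{r.level}: observed {r.observed.pct:.1f}% vs predicted "
              f"{r.predicted.pct:.1f}% -> gap {r.diff_pp:.1f} pp, "
              f"{r.additional_patients:,} additional patients ({ratio})")

    org_df, extrema = G.per_org_gaps(cohort, reference)
    org_df.to_csv(RESULTS / "gap_by_org.csv", index=False, float_format="%.4f")
    for level in LEVELS:
        ext = extrema[(level, "org_comorbidity")]
        print(f"cross-org gap range at {level}: "
              f"{ext['min']:.1f} to {ext['max']:.1f} pp")


if __name__ == "__main__":
    main()
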