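"""Simulate the study cohort.

Generates a 50,000-patient synthetic ambulatory population across 25
organizations with known true hypertension and comorbidity status, plus
the reference prevalence table implied by the generator's own truth.
Patient-level tables go to scratch/cohort/; a small summary of the
simulation lands in results/simulation_summary.json.
"""
from __future__ import annotations

from _common import STUDY_PARAMS, ensure_cohort, save_json


def main() -> None:
    cohort, reference = ensure_cohort()
    truth_mean = None
    import pandas as pd
    from _common import SCRATCH
    truth = pd.read_csv(SCRATCH / "ground_truth.csv")
    summary = {
        "n_patients": int(len(cohort.patients)),
        "n_orgs": int(cohort.patients["org_id"].nunique()),
        "observation_year": cohort.observation_year,
        "seed": STUDY_PARAMS.seed,
        "true_htn_prevalence": float(truth["true_htn"].mean()),
        "true_obesity": float(truth["true_obesity"].mean()),
        "true_diabetes": float(truth["true_diabetes"].mean()),
        "true_ckd": float(truth["true_ckd"].mean()),
        "n_encounters": int(len(cohort.encounters)),
        "n_bp_readings": int(len(cohort.bp_readings)),
        "n_diagnoses": int(len(cohort.diagnoses)),
    }
    path = save_json("simulation_summary.json", summary)
    print(f"cohort ready: {summary['n_patients']} patients, "
          f"true hypertension prevalence {100 * summary['true_htn_prevalence']:.1f}%")
    print(f"summary -> {path}")


if __name__ == "__main__":
    main()
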