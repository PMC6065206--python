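"""Shared plumbing for the numbered analysis scripts.

The simulated study cohort lives under scratch/ (large, regenerable);
summary tables land under results/ (small, text). Every script can run
standalone: if the cohort is missing it is regenerated deterministically.
"""
from __future__ import annotations

import json
from pathlib import Path

from htngap.cohort import Cohort, read_cohort, write_cohort
from htngap.estimator import ReferenceTable
from htngap.simulate import SimulationParams, generate_cohort, generate_reference_table

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

#: The study conditions for the main analysis: a 50,000-patient scaled-down
#: analogue of the 8.92M-patient, 25-organization application population.
STUDY_PARAMS = SimulationParams(n_patients=50_000, org_count=25, seed=20160101)


def ensure_cohort() -> tuple[Cohort, ReferenceTable]:
    RESULTS.mkdir(exist_ok=True)
    if not (SCRATCH / "patients.csv").exists():
        print(f"simulating {STUDY_PARAMS.n_patients} patients "
              f"across {STUDY_PARAMS.org_count} organizations ...")
        cohort, truth = generate_cohort(STUDY_PARAMS)
        SCRATCH.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, SCRATCH)
        truth.to_csv(SCRATCH / "ground_truth.csv", index=False)
        generate_reference_table(STUDY_PARAMS).write(
            SCRATCH / "reference_table.csv", SCRATCH / "reference_buckets.csv")
    cohort = read_cohort(SCRATCH, STUDY_PARAMS.observation_year)
    reference = ReferenceTable.read(SCRATCH / "reference_table.csv",
                                    SCRATCH / "reference_buckets.csv")
    return cohort, reference


def save_json(name: str, payload: dict) -> Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
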