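"""Re-derive the published application's headline arithmetic.

The 2016 application of the Million Hearts Hypertension Prevalence
Estimator (8.92 million patients, 25 organizations) printed observed and
predicted prevalences whose patient-level inputs are proprietary; this
script treats the printed prevalences as fixed inputs and recomputes every
derived quantity: observed counts in millions, percentage-point gaps,
additional-patient counts, one-in-N ratios, and cross-organization
extrema. Writes results/published_arithmetic.json.
"""
from __future__ import annotations

from htngap import gap as G
from htngap.published import STUDY_N, load_overall_estimates, org_estimates_long

from _common import save_json


def main() -> None:
    overall = load_overall_estimates().set_index("level")
    payload: dict = {"n": STUDY_N, "levels": {}}
    for level, row in overall.iterrows():
        org = G.compare_percentages(row.observed_pct, row.predicted_org_pct, STUDY_N)
        ref = G.compare_percentages(row.observed_pct, row.predicted_ref_pct, STUDY_N)
        payload["levels"][level] = {
            "observed_pct": row.observed_pct,
            "observed_millions": G.millions2(row.observed_pct / 100 * STUDY_N),
            "org_mode": {"diff_pp": round(org.diff_pp, 10),
                         "additional_patients": org.additional_patients,
                         "one_in_n": org.one_in_n},
            "reference_mode": {"diff_pp": round(ref.diff_pp, 10),
                               "additional_patients": ref.additional_patients,
                               "one_in_n": ref.one_in_n},
        }
        print(f"{level}: observed {row.observed_pct}% "
              f"({payload['levels'][level]['observed_millions']}M), "
              f"gap {org.diff_pp:.1f} pp -> {org.additional_patients:,} patients, "
              f"one in {org.one_in_n}")

    _, extrema = G.gaps_from_prevalence_table(org_estimates_long(), n=100_000)
    payload["cross_org_max_diff_pp"] = {lev: ext["max"] for lev, ext in extrema.items()}
    print("cross-org maxima:", payload["cross_org_max_diff_pp"])
    path = save_json("published_arithmetic.json", payload)
    print(f"-> {path}")


if __name__ == "__main__":
    main()
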