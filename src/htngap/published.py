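"""Published summary estimates from the 2016 multi-organization application
of the Million Hearts Hypertension Prevalence Estimator.

These are the *printed* overall and organization-level observed/predicted
hypertension prevalences from that application (8.92 million patients, 25
U.S. health care delivery organizations). The underlying patient-level
data are proprietary and cannot be re-derived; the prevalences therefore
enter this package only as fixed inputs to downstream gap arithmetic
(percentage-point differences, additional-patient counts, one-in-N
ratios, cross-organization extrema).
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .types import LEVELS

#: Total patients in the published application.
STUDY_N = 8_920_000
STUDY_N_MILLIONS = 8.92


def _load(name: str) -> pd.DataFrame:
    with resources.files("htngap.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_overall_estimates() -> pd.DataFrame:
    """Overall observed and predicted prevalence (%) per evidence level.

    ``predicted_org`` columns use organization-specific comorbidity data,
    ``predicted_ref`` columns use the reference population's comorbidity
    estimates; CI bounds are the printed 95% intervals.
    """
    return _load("overall_estimates.csv")


def load_org_estimates() -> pd.DataFrame:
    """Organization-level observed and predicted prevalence (%), wide format."""
    return _load("org_estimates.csv")


def org_estimates_long() -> pd.DataFrame:
    """Organization-level estimates reshaped for gap arithmetic.

    One row per (org_id, level) with observed_pct and predicted_pct, using
    organization-specific comorbidity predictions.
    """
    wide = load_org_estimates()
    pairs = {
        "claims_only": ("observed_claims_pct", "predicted_claims_pct"),
        "plus_problem_list": ("observed_claims_pl_pct", "predicted_claims_pl_pct"),
        "plus_clinical": ("observed_all_pct", "predicted_all_pct"),
    }
    rows = []
    for level in LEVELS:
        obs_col, pred_col = pairs[level]
        for r in wide.itertuples(index=False):
            rows.append({"org_id": r.org_id, "level": level,
                         "observed_pct": getattr(r, obs_col),
                         "predicted_pct": getattr(r, pred_col)})
    return pd.DataFrame(rows)
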