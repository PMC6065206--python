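from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from htngap.cohort import Cohort

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def _d(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


@pytest.fixture
def ten_patient_cohort() -> Cohort:
    """Hand-built 10-patient cohort: 2 under-age, 1 with only non-E&M visits,
    1 whose only visit predates the observation year, 6 eligible."""
    patients = pd.DataFrame(
        [("p01", "org1", "female", 30, "nh_white"),
         ("p02", "org1", "male", 45, "nh_black"),
         ("p03", "org1", "female", 67, "hispanic"),
         ("p04", "org2", "male", 80, "other"),
         ("p05", "org2", "female", 52, "missing"),
         ("p06", "org2", "male", 18, "nh_white"),
         ("p07", "org1", "female", 17, "nh_white"),   # under-age
         ("p08", "org2", "male", 16, "nh_black"),     # under-age
         ("p09", "org1", "female", 40, "nh_white"),   # only 'other' encounters
         ("p10", "org2", "male", 60, "nh_white")],    # visit in prior year
        columns=["patient_id", "org_id", "sex", "age", "race_ethnicity"])
    encounters = pd.DataFrame(
        [("p01", _d("2016-03-01"), "ambulatory_em"),
         ("p02", _d("2016-04-02"), "ambulatory_em"),
         ("p03", _d("2016-05-03"), "ambulatory_em"),
         ("p04", _d("2016-06-04"), "ambulatory_em"),
         ("p05", _d("2016-07-05"), "ambulatory_em"),
         ("p06", _d("2016-08-06"), "ambulatory_em"),
         ("p07", _d("2016-09-07"), "ambulatory_em"),
         ("p08", _d("2016-10-08"), "ambulatory_em"),
         ("p09", _d("2016-11-09"), "other"),
         ("p10", _d("2015-12-10"), "ambulatory_em")],
        columns=["patient_id", "date", "setting"])
    diagnoses = pd.DataFrame(
        [("p01", _d("2016-03-01"), "I10", "claim"),
         ("p01", _d("2016-03-15"), "I10", "problem_list"),
         ("p02", _d("2016-04-02"), "I11.0", "problem_list"),
         ("p03", _d("2016-05-03"), "E66.9", "claim"),
         ("p04", _d("2016-06-04"), "E11.9", "claim")],
        columns=["patient_id", "date", "code", "source"])
    bp_readings = pd.DataFrame(
        [("p03", _d("2016-05-03"), 150, 95),
         ("p03", _d("2016-05-20"), 142, 90),
         ("p04", _d("2016-06-04"), 120, 80),
         ("p05", _d("2016-07-05"), 165, 88)],
        columns=["patient_id", "date", "systolic", "diastolic"])
    measurements = pd.DataFrame(
        [("p04", _d("2016-06-04"), "bmi", 31.2),
         ("p06", _d("2016-08-06"), "egfr", 45.0)],
        columns=["patient_id", "date", "kind", "value"])
    return Cohort(patients=patients, encounters=encounters, diagnoses=diagnoses,
                  bp_readings=bp_readings, measurements=measurements,
                  observation_year=2016)
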