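"""Patient-level cohort container: domain types, CSV I/O, eligibility, demographics.

A cohort is five relational tables (patients, encounters, diagnoses,
blood-pressure readings, clinical measurements) plus an observation year.
Dates are ISO-8601 calendar dates; comparisons never involve time of day.
Age is age at January 1 of the observation year, stored directly.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

SEXES = ("female", "male")
RACE_ETHNICITIES = ("nh_white", "nh_black", "hispanic", "other", "missing")
KNOWN_RACES = ("nh_white", "nh_black", "hispanic", "other")
SETTINGS = ("ambulatory_em", "other")
DIAGNOSIS_SOURCES = ("claim", "problem_list")
MEASUREMENT_KINDS = ("bmi", "hba1c", "fasting_glucose", "egfr")

#: Age bands partitioning the analyzable range 18-85.
AGE_GROUPS = ("18-44", "45-64", "65-74", "75-85")
_AGE_BOUNDS = {"18-44": (18, 44), "45-64": (45, 64), "65-74": (65, 74), "75-85": (75, 85)}

# ICD-10-CM shape: letter, two digits, optional dot plus 1-4 alphanumerics.
_ICD10_RE = re.compile(r"^[A-Z][0-9][0-9A-Z](?:\.[0-9A-Z]{1,4})?$")

TABLE_NAMES = ("patients", "encounters", "diagnoses", "bp_readings", "measurements")
TABLE_COLUMNS = {
    "patients": ["patient_id", "org_id", "sex", "age", "race_ethnicity"],
    "encounters": ["patient_id", "date", "setting"],
    "diagnoses": ["patient_id", "date", "code", "source"],
    "bp_readings": ["patient_id", "date", "systolic", "diastolic"],
    "measurements": ["patient_id", "date", "kind", "value"],
}


class CohortValidationError(ValueError):
    """Raised when cohort tables violate schema or invariants.

    ``problems`` is a list of human-readable ``file:row: message`` strings.
    """

    def __init__(self, problems: list[str]):
        self.problems = problems
        shown = problems[:20]
        more = f"\n... and {len(problems) - 20} more" if len(problems) > 20 else ""
        super().__init__(
            f"{len(problems)} cohort validation problem(s):\n" + "\n".join(shown) + more
        )


def age_group(age: int) -> str:
    """Return the age band containing ``age``; ages outside 18-85 are an error."""
    age = int(age)
    for band, (lo, hi) in _AGE_BOUNDS.items():
        if lo <= age <= hi:
            return band
    raise ValueError(f"age {age} outside the analyzable range [18, 85]")


@dataclass
class Cohort:
    """Five patient-level tables plus the observation year.

    Child rows must reference an existing patient_id; rows may carry dates
    outside the observation year — restricting evidence to the year is the
    job of downstream operations, not of the container.
    """

    patients: pd.DataFrame
    encounters: pd.DataFrame
    diagnoses: pd.DataFrame
    bp_readings: pd.DataFrame
    measurements: pd.DataFrame
    observation_year: int

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @classmethod
    def empty(cls, observation_year: int) -> "Cohort":
        frames = {}
        for name, cols in TABLE_COLUMNS.items():
            df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
            if "date" in cols:
                df["date"] = pd.Series(dtype="datetime64[ns]")
            frames[name] = df
        return cls(observation_year=observation_year, **frames)

    def validate(self) -> list[str]:
        return _validate_tables(
            {name: self.table(name) for name in TABLE_NAMES},
            file_names={name: f"{name}.csv" for name in TABLE_NAMES},
        )

    def check(self) -> "Cohort":
        problems = self.validate()
        if problems:
            raise CohortValidationError(problems)
        return self


def _check_rows(df: pd.DataFrame, mask: pd.Series, file: str, message) -> list[str]:
    out = []
    for idx in df.index[mask.fillna(True)]:
        msg = message(df.loc[idx]) if callable(message) else message
        # +2: header line plus 1-based numbering, matching the file on disk
        out.append(f"{file}:row {idx + 2}: {msg}")
    return out


def _validate_tables(tables: Mapping[str, pd.DataFrame], file_names: Mapping[str, str]) -> list[str]:
    problems: list[str] = []
    pat = tables["patients"]
    f = file_names["patients"]

    dup = pat["patient_id"].duplicated(keep=False)
    problems += _check_rows(pat, dup & ~pat["patient_id"].duplicated(), f,
                            lambda r: f"duplicate patient_id {r['patient_id']!r}")
    problems += _check_rows(pat, ~pat["sex"].isin(SEXES), f,
                            lambda r: f"sex {r['sex']!r} not in {SEXES}")
    problems += _check_rows(pat, ~pat["race_ethnicity"].isin(RACE_ETHNICITIES), f,
                            lambda r: f"race_ethnicity {r['race_ethnicity']!r} not in {RACE_ETHNICITIES}")
    age_num = pd.to_numeric(pat["age"], errors="coerce")
    bad_age = age_num.isna() | (age_num < 0) | (age_num != age_num.round())
    problems += _check_rows(pat, bad_age, f, lambda r: f"age {r['age']!r} is not a non-negative integer")

    known_ids = set(pat.loc[~dup, "patient_id"]) | set(pat["patient_id"])

    for name in ("encounters", "diagnoses", "bp_readings", "measurements"):
        df, fn = tables[name], file_names[name]
        problems += _check_rows(df, ~df["patient_id"].isin(known_ids), fn,
                                lambda r: f"patient_id {r['patient_id']!r} not present in patients table")
        if not pd.api.types.is_datetime64_any_dtype(df["date"]):
            dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
        else:
            dates = df["date"]
        problems += _check_rows(df, dates.isna(), fn,
                                lambda r: f"date {r['date']!r} is not a valid ISO-8601 calendar date")

    enc = tables["encounters"]
    problems += _check_rows(enc, ~enc["setting"].isin(SETTINGS), file_names["encounters"],
                            lambda r: f"setting {r['setting']!r} not in {SETTINGS}")

    dx = tables["diagnoses"]
    fdx = file_names["diagnoses"]
    problems += _check_rows(dx, ~dx["source"].isin(DIAGNOSIS_SOURCES), fdx,
                            lambda r: f"source {r['source']!r} not in {DIAGNOSIS_SOURCES}")
    code_ok = dx["code"].astype(str).str.match(_ICD10_RE)
    problems += _check_rows(dx, ~code_ok, fdx,
                            lambda r: f"code {r['code']!r} does not match the ICD-10-CM shape")

    bp = tables["bp_readings"]
    fbp = file_names["bp_readings"]
    sys_ = pd.to_numeric(bp["systolic"], errors="coerce")
    dia = pd.to_numeric(bp["diastolic"], errors="coerce")
    bad_bp = (
        sys_.isna() | dia.isna()
        | (sys_ < 40) | (sys_ > 300) | (dia < 20) | (dia > 200) | (dia >= sys_)
    )
    problems += _check_rows(bp, bad_bp, fbp,
                            lambda r: f"BP {r['systolic']}/{r['diastolic']} violates "
                                      "40<=systolic<=300, 20<=diastolic<=200, diastolic<systolic")

    meas = tables["measurements"]
    fm = file_names["measurements"]
    problems += _check_rows(meas, ~meas["kind"].isin(MEASUREMENT_KINDS), fm,
                            lambda r: f"kind {r['kind']!r} not in {MEASUREMENT_KINDS}")
    val = pd.to_numeric(meas["value"], errors="coerce")
    problems += _check_rows(meas, val.isna() | (val <= 0), fm,
                            lambda r: f"value {r['value']!r} is not a positive number")
    return problems


def _resolve_paths(paths: Mapping[str, str | Path] | str | Path) -> dict[str, Path]:
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        return {name: base / f"{name}.csv" for name in TABLE_NAMES}
    out = {name: Path(paths[name]) for name in TABLE_NAMES}
    return out


def read_cohort(paths: Mapping[str, str | Path] | str | Path, observation_year: int) -> Cohort:
    """Read and validate a cohort from five CSV files.

    ``paths`` is either a directory containing the standard file names
    (patients.csv, encounters.csv, ...) or a mapping table-name -> path.
    Any invariant violation is reported with file and row number.
    """
    resolved = _resolve_paths(paths)
    problems: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    for name, path in resolved.items():
        if not path.exists():
            raise FileNotFoundError(f"cohort table file not found: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        expected = TABLE_COLUMNS[name]
        if list(df.columns) != expected:
            raise CohortValidationError(
                [f"{path.name}: malformed header {list(df.columns)}, expected {expected}"]
            )
        tables[name] = df

    problems = _validate_tables(tables, {name: p.name for name, p in resolved.items()})
    if problems:
        raise CohortValidationError(problems)

    # Typed conversion after validation has passed.
    pat = tables["patients"].copy()
    pat["age"] = pat["age"].astype(int)
    typed = {"patients": pat}
    for name in ("encounters", "diagnoses", "bp_readings", "measurements"):
        df = tables[name].copy()
        df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
        typed[name] = df
    typed["bp_readings"]["systolic"] = typed["bp_readings"]["systolic"].astype(int)
    typed["bp_readings"]["diastolic"] = typed["bp_readings"]["diastolic"].astype(int)
    typed["measurements"]["value"] = typed["measurements"]["value"].astype(float)
    return Cohort(observation_year=int(observation_year), **typed)


def write_cohort(cohort: Cohort, paths: Mapping[str, str | Path] | str | Path) -> None:
    """Write the five cohort tables as CSV; round-trips exactly through read_cohort."""
    resolved = _resolve_paths(paths)
    for name, path in resolved.items():
        path.parent.mkdir(parents=True, exist_ok=True)
        df = cohort.table(name).copy()
        if "date" in df.columns and len(df):
            df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
        df.to_csv(path, index=False)


def eligible_patients(cohort: Cohort) -> set[str]:
    """Patients aged 18-85 with >=1 ambulatory E&M visit in the observation year."""
    pat = cohort.patients
    in_age = pat["age"].astype(int).between(18, 85)
    enc = cohort.encounters
    if len(enc):
        dates = pd.to_datetime(enc["date"])
        in_year = dates.dt.year == cohort.observation_year
        visited = set(enc.loc[in_year & (enc["setting"] == "ambulatory_em"), "patient_id"])
    else:
        visited = set()
    return set(pat.loc[in_age, "patient_id"]) & visited


def summarize_demographics(cohort: Cohort, eligible: Iterable[str]) -> pd.DataFrame:
    """Percentage composition by age group, sex and race/ethnicity.

    Returns one row per (org_id, characteristic, category) with counts and
    percentages; ``org_id == "overall"`` aggregates all organizations, and a
    ``characteristic == "total"`` row carries the denominator. Within each
    characteristic the percentages sum to 100 (up to rounding).
    """
    eligible = set(eligible)
    if not eligible:
        raise ValueError("eligible set is empty; cannot summarize demographics")
    pat = cohort.patients
    missing = eligible - set(pat["patient_id"])
    if missing:
        raise ValueError(f"eligible ids not in cohort: {sorted(missing)[:5]}")
    sub = pat[pat["patient_id"].isin(eligible)].copy()
    sub["age_group"] = sub["age"].astype(int).map(age_group)

    rows = []

    def emit(org: str, frame: pd.DataFrame) -> None:
        n = len(frame)
        rows.append({"org_id": org, "characteristic": "total", "category": "n",
                     "count": n, "pct": 100.0})
        for char, cats in (("age_group", AGE_GROUPS), ("sex", SEXES),
                           ("race_ethnicity", RACE_ETHNICITIES)):
            counts = frame[char].value_counts()
            for cat in cats:
                c = int(counts.get(cat, 0))
                rows.append({"org_id": org, "characteristic": char, "category": cat,
                             "count": c, "pct": 100.0 * c / n})

    emit("overall", sub)
    for org, frame in sub.groupby("org_id", sort=True):
        emit(str(org), frame)
    return pd.DataFrame(rows, columns=["org_id", "characteristic", "category", "count", "pct"])
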