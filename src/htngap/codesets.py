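"""Configurable ICD-10-CM code prefixes, clinical thresholds and BP criteria.

Code matching is prefix-based on the undotted code string (prefix ``I10``
matches ``I10``; ``I11`` matches ``I11.0``). Defaults follow common
claims-algorithm practice and are meant to be overridden per deployment via
YAML — code lists are site policy, not package policy.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

from .types import CONDITIONS


@dataclass(frozen=True)
class CodeSets:
    hypertension_prefixes: tuple[str, ...] = ("I10", "I11", "I12", "I13", "I15", "I16")
    obesity_prefixes: tuple[str, ...] = ("E66",)
    diabetes_prefixes: tuple[str, ...] = ("E10", "E11")
    ckd_prefixes: tuple[str, ...] = ("N18",)

    # Clinical criteria thresholds.
    bmi_cut: float = 30.0                 # kg/m^2, any single measurement
    hba1c_cut: float = 6.5                # %, any single measurement
    fasting_glucose_cut: float = 126.0    # mg/dL, two distinct dates required
    egfr_cut: float = 60.0                # mL/min/1.73 m^2, below-threshold
    egfr_chronicity_days: int = 90        # two low eGFRs at least this far apart

    # Office-BP case-definition thresholds (systolic, diastolic), mm Hg.
    bp_single: tuple[int, int] = (160, 100)   # one reading suffices
    bp_repeat: tuple[int, int] = (140, 90)    # two readings on distinct days
    # False: a reading qualifies if systolic OR diastolic exceeds its cut
    # (standard staging convention); True requires both components.
    bp_require_both: bool = False

    def __post_init__(self) -> None:
        for cond in ("hypertension",) + CONDITIONS:
            if not self.prefixes(cond):
                raise ValueError(f"empty code prefix list for {cond}")
        for name in ("bmi_cut", "hba1c_cut", "fasting_glucose_cut", "egfr_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.egfr_chronicity_days <= 0:
            raise ValueError("egfr_chronicity_days must be positive")

    def prefixes(self, condition: str) -> tuple[str, ...]:
        try:
            return getattr(self, f"{condition}_prefixes")
        except AttributeError:
            raise KeyError(f"unknown condition {condition!r}") from None

    def with_overrides(self, **kwargs) -> "CodeSets":
        return replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeSets":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)


DEFAULT_CODE_SETS = CodeSets()
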