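"""Shared enumerations and result containers used across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass

#: Evidence levels, in increasing order of data used for ascertainment.
LEVELS = ("claims_only", "plus_problem_list", "plus_clinical")
LEVEL_RANK = {lev: i for i, lev in enumerate(LEVELS)}

#: Mutually exclusive hypertension case-definition tiers. A patient is
#: assigned the first tier whose criterion is met, in this order.
TIERS = ("claims", "problem_list", "bp_criteria", "none")

#: Which tiers count as hypertensive at each evidence level (nested unions).
ADMISSIBLE_TIERS = {
    "claims_only": frozenset({"claims"}),
    "plus_problem_list": frozenset({"claims", "problem_list"}),
    "plus_clinical": frozenset({"claims", "problem_list", "bp_criteria"}),
}

#: Comorbidity-count buckets (number of ascertained conditions among
#: obesity, diabetes, chronic kidney disease).
BUCKETS = ("zero", "one", "two_or_three")

CONDITIONS = ("obesity", "diabetes", "ckd")


def count_bucket(n_conditions: int) -> str:
    """Map a count of ascertained conditions (0..3) to its bucket."""
    if n_conditions < 0 or n_conditions > 3:
        raise ValueError(f"condition count must be in 0..3, got {n_conditions}")
    if n_conditions == 0:
        return "zero"
    if n_conditions == 1:
        return "one"
    return "two_or_three"


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A proportion with a 95% confidence interval and its denominator.

    ``value``, ``ci_low`` and ``ci_high`` are fractions in [0, 1];
    ``n`` is the denominator count.
    """

    value: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.value <= self.ci_high <= 1.0):
            raise ValueError(
                f"require 0 <= ci_low <= value <= ci_high <= 1, got "
                f"({self.ci_low}, {self.value}, {self.ci_high})"
            )
        if self.n < 0:
            raise ValueError("denominator must be non-negative")

    @property
    def pct(self) -> float:
        return 100.0 * self.value
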