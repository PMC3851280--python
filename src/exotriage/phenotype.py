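"""Missing-data-adjusted phenotype rates and cost-per-diagnosis arithmetic."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .model import PHENOTYPE_TRAITS, PhenotypeCode, PhenotypeTable


@dataclass(frozen=True)
class RateResult:
    """A positive-finding rate with no-data entries removed from the denominator."""

    numerator: int
    denominator: int
    percent: int

    def to_dict(self) -> dict:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "percent": self.percent,
        }


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def missing_adjusted_rate(column: Sequence[PhenotypeCode]) -> RateResult:
    """Percent positive among entries with data; ND entries shrink the denominator.

    Percent is rounded to the nearest integer, half away from zero.
    """
    if not column:
        raise ValueError("empty phenotype column")
    numerator = sum(1 for code in column if code is PhenotypeCode.POSITIVE)
    denominator = sum(1 for code in column if code is not PhenotypeCode.ND)
    if denominator == 0:
        raise ValueError("rate undefined: every entry is ND")
    return RateResult(
        numerator=numerator,
        denominator=denominator,
        percent=_round_half_away(100.0 * numerator / denominator),
    )


def all_rates(table: PhenotypeTable) -> dict[str, RateResult]:
    """Missing-adjusted rate for every trait column of the phenotype grid."""
    rates = {}
    for trait in PHENOTYPE_TRAITS:
        try:
            rates[trait] = missing_adjusted_rate(table.column(trait))
        except ValueError as exc:
            raise ValueError(f"column {trait!r}: {exc}") from None
    return rates


def cost_per_diagnosis(test_cost: float, diagnosis_rate: float) -> int:
    """Whole-dollar cost per diagnosis, truncated toward zero."""
    if test_cost <= 0:
        raise ValueError(f"test_cost must be positive, got {test_cost}")
    if not 0.0 < diagnosis_rate <= 1.0:
        raise ValueError(f"diagnosis_rate must be in (0, 1], got {diagnosis_rate}")
    return int(test_cost / diagnosis_rate)


def prioritized_fraction(mean_prioritized: float, mean_called: float) -> float:
    """Percentage of called variants surviving prioritization, to 2 decimals."""
    if mean_called <= 0:
        raise ValueError("mean_called must be positive")
    if mean_prioritized <= 0:
        raise ValueError("mean_prioritized must be positive")
    if mean_prioritized > mean_called:
        raise ValueError("mean_prioritized cannot exceed mean_called")
    return round(100.0 * mean_prioritized / mean_called, 2)
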