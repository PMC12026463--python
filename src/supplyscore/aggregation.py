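"""Weighted aggregation of the seven indicators into the overall risk score.

ORS = (I_1 W_1 + ... + I_7 W_7) * 100 with normalized indicator values
I_i in [0, 1] and fractional weights W_i summing to 1.  Weights of
missing indicators are redistributed proportionally over the present
ones so the effective weights always sum to 100%.  The ORS is binned
into three supplier risk categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .errors import ValidationError

INDICATOR_IDS = (
    "hazard_risk",
    "cvs",
    "incident_category",
    "audit",
    "lpi",
    "gdp_per_capita",
    "gdp_growth",
)

#: Recommended weights, in percent.
DEFAULT_WEIGHTS = {
    "hazard_risk": 50.0,
    "cvs": 20.0,
    "incident_category": 10.0,
    "audit": 5.0,
    "lpi": 5.0,
    "gdp_per_capita": 5.0,
    "gdp_growth": 5.0,
}

_SUM_TOL = 1e-9


class SupplierCategory(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    RISKY = "risky"


@dataclass(frozen=True)
class WeightConfig:
    """Percentage weight per indicator; non-negative and summing to 100."""

    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(INDICATOR_IDS)
        if unknown:
            raise ValidationError(
                f"unknown indicator id(s) in weights: {sorted(unknown)}; "
                f"valid ids: {list(INDICATOR_IDS)}"
            )
        missing = set(INDICATOR_IDS) - set(self.weights)
        if missing:
            raise ValidationError(f"weights missing indicator id(s): {sorted(missing)}")
        for ind, w in self.weights.items():
            if w < 0:
                raise ValidationError(f"weight for '{ind}' is negative: {w}")
        total = sum(self.weights.values())
        if abs(total - 100.0) > _SUM_TOL:
            raise ValidationError(f"weights must sum to 100, got {total}")

    def __getitem__(self, indicator: str) -> float:
        return self.weights[indicator]


@dataclass(frozen=True)
class IndicatorVector:
    """The seven named indicators, each a normalized value in [0, 1] or None.

    None marks a missing indicator (no data); it is distinct from 0,
    which is a legal minimal-risk value (e.g. a perfect LPI of 5).
    """

    values: Mapping[str, float | None]

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(INDICATOR_IDS)
        if unknown:
            raise ValidationError(
                f"unknown indicator id(s): {sorted(unknown)}; valid ids: "
                f"{list(INDICATOR_IDS)}"
            )
        for ind, v in self.values.items():
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"indicator '{ind}' value {v} outside the normalized range [0,1]"
                )
        if not self.present:
            raise ValidationError("at least one indicator must be present")

    @property
    def present(self) -> dict[str, float]:
        return {
            ind: self.values[ind]
            for ind in INDICATOR_IDS
            if self.values.get(ind) is not None
        }

    @property
    def missing(self) -> list[str]:
        return [ind for ind in INDICATOR_IDS if self.values.get(ind) is None]

    def __getitem__(self, indicator: str) -> float | None:
        return self.values.get(indicator)


@dataclass(frozen=True)
class RiskReport:
    """Result of one supplier assessment.

    effective_weights are fractions over the present indicators (sum 1);
    contributions are the weighted terms I_i * W_i whose sum * 100 is the
    overall_risk_score (a percentage).
    """

    supplier_id: str
    effective_weights: dict[str, float]
    contributions: dict[str, float]
    overall_risk_score: float
    category: SupplierCategory
    missing_indicators: list[str]
    indicator_values: dict[str, float]

    def is_borderline(self, margin: float = 2.0) -> bool:
        """Whether the score sits within ``margin`` points of a category
        boundary, warranting human review."""
        return any(
            abs(self.overall_risk_score - b) < margin for b in (50.0, 70.0)
        )


def redistribute_weights(
    weights: WeightConfig | Mapping[str, float], missing: Iterable[str]
) -> dict[str, float]:
    """Effective fractional weights after dropping the missing indicators.

    Each remaining percentage weight is scaled by 100 / (100 - sum of
    missing weights) and converted to a fraction; the result sums to 1
    and preserves the pairwise ratios of the remaining weights.
    """
    if not isinstance(weights, WeightConfig):
        weights = WeightConfig(dict(weights))
    missing = set(missing)
    unknown = missing - set(INDICATOR_IDS)
    if unknown:
        raise ValidationError(f"unknown indicator id(s) marked missing: {sorted(unknown)}")
    remaining = [ind for ind in INDICATOR_IDS if ind not in missing]
    if not remaining:
        raise ValidationError("all indicators are missing; nothing to score")
    remaining_total = sum(weights[ind] for ind in remaining)
    if remaining_total <= 0:
        raise ValidationError(
            "the remaining indicators carry zero total weight; cannot redistribute"
        )
    return {ind: weights[ind] / remaining_total for ind in remaining}


def categorize_supplier(ors: float) -> SupplierCategory:
    """Band the ORS: < 50% low, [50, 70)% moderate, >= 70% risky.

    Boundary scores take the worse band (50 -> moderate, 70 -> risky).
    Scores below the default-weight floor of 33.63% — attainable under
    custom weights — are still low risk.
    """
    if not (0.0 <= ors <= 100.0):
        raise ValidationError(f"overall risk score out of range [0,100]: {ors}")
    if ors < 50.0:
        return SupplierCategory.LOW
    if ors < 70.0:
        return SupplierCategory.MODERATE
    return SupplierCategory.RISKY


def overall_risk_score(
    indicators: IndicatorVector | Mapping[str, float | None],
    weights: WeightConfig | Mapping[str, float] | None = None,
    supplier_id: str = "",
) -> RiskReport:
    """Score a supplier from its indicator vector.

    Redistributes the configured weights over the present indicators,
    computes ORS = sum(I_i * W_i_effective) * 100 at full precision, and
    attaches the per-indicator contributions and the risk category.
    Rounding to one decimal is presentation-level only.
    """
    if not isinstance(indicators, IndicatorVector):
        indicators = IndicatorVector(dict(indicators))
    if weights is None:
        weights = WeightConfig()
    elif not isinstance(weights, WeightConfig):
        weights = WeightConfig(dict(weights))
    effective = redistribute_weights(weights, indicators.missing)
    present = indicators.present
    contributions = {ind: present[ind] * w for ind, w in effective.items()}
    ors = sum(contributions.values()) * 100.0
    # guard against float drift at the extremes
    ors = min(max(ors, 0.0), 100.0)
    return RiskReport(
        supplier_id=supplier_id,
        effective_weights=effective,
        contributions=contributions,
        overall_risk_score=ors,
        category=categorize_supplier(ors),
        missing_indicators=indicators.missing,
        indicator_values=dict(present),
    )
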