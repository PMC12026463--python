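"""Indicators 2-7: commodity vulnerability, incident category level, audit
performance, and the three country-level economic indicators.

Each sub-assessment produces a normalized risk value in [0, 1]; higher is
riskier.  Indicators with no data raise :class:`MissingIndicator` so the
aggregation layer can redistribute their weight instead of scoring zero.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from dateutil.relativedelta import relativedelta

from .errors import MissingIndicator, ValidationError


class IncidentCategory(str, Enum):
    """Where in the supply chain a non-conformity was detected."""

    CONTROL = "control"
    RECALL = "recall"
    OUTBREAK = "outbreak"
    FRAUD = "fraud"
    CONSUMER_COMPLAINT = "consumer_complaint"
    OTHER = "other"


# Severity points: 1 low, 2 low-medium, 3 medium-high, 4 high.
_INCIDENT_POINTS = {
    IncidentCategory.CONTROL: 1,
    IncidentCategory.RECALL: 3,
    IncidentCategory.OUTBREAK: 4,
    IncidentCategory.FRAUD: 3,
    IncidentCategory.CONSUMER_COMPLAINT: 1,
    IncidentCategory.OTHER: 2,
}


class AuditLevel(str, Enum):
    MINOR = "minor"
    MAJOR = "major"
    CRITICAL = "critical"


_AUDIT_METRIC = {
    AuditLevel.MINOR: 0.3,
    AuditLevel.MAJOR: 0.7,
    AuditLevel.CRITICAL: 1.0,
}


@dataclass(frozen=True)
class IncidentRecord:
    """One dated food-safety incident notification."""

    date: dt.date
    commodity: str
    incident_category: IncidentCategory


@dataclass(frozen=True)
class AuditFinding:
    """One audit non-conformity at a given severity level."""

    level: AuditLevel


@dataclass(frozen=True)
class CountryEconomics:
    """Country-level economic figures; each field independently optional.

    lpi: World Bank Logistics Performance Index, in [1, 5] (higher is
    better logistics).  gdp_per_capita: USD.  gdp_growth: % per annum.
    """

    lpi: float | None = None
    gdp_per_capita: float | None = None
    gdp_growth: float | None = None

    def __post_init__(self) -> None:
        if self.lpi is not None and not (1.0 <= self.lpi <= 5.0):
            raise ValidationError(f"lpi out of range [1,5]: {self.lpi}")
        if self.gdp_per_capita is not None and self.gdp_per_capita < 0:
            raise ValidationError(
                f"gdp_per_capita must be non-negative, got {self.gdp_per_capita}"
            )


def window_contains(date: dt.date, as_of: dt.date) -> bool:
    """True when ``date`` falls in the half-open window (as_of - 12 months, as_of]."""
    return as_of - relativedelta(months=12) < date <= as_of


def select_window(
    incidents: Iterable[IncidentRecord], as_of: dt.date
) -> list[IncidentRecord]:
    """Incidents in the 12 calendar months up to and including ``as_of``.

    The window is half-open: (as_of - 12 months, as_of].  A full year is
    used so seasonal commodities (e.g. summer fruit harvests) are not
    under- or over-represented.
    """
    return [r for r in incidents if window_contains(r.date, as_of)]


def compute_cvs(commodity_incidents: int, total_incidents: int) -> float:
    """Commodity vulnerability score: (commodity / total) * 100, a percentage."""
    if total_incidents == 0:
        raise MissingIndicator("cvs", "no incidents in the window")
    if commodity_incidents < 0 or total_incidents < 0:
        raise ValidationError("incident counts must be non-negative")
    if commodity_incidents > total_incidents:
        raise ValidationError(
            f"commodity incidents ({commodity_incidents}) exceed total "
            f"({total_incidents})"
        )
    return commodity_incidents / total_incidents * 100.0


def normalize_cvs(cvs: float) -> float:
    """Use the CVS percentage numeral directly as the [0, 1] indicator.

    A CVS of 0.04% contributes 0.04; commodities accounting for more than
    1% of all incidents are clamped to 1.0.
    """
    if cvs < 0:
        raise ValidationError(f"CVS must be non-negative, got {cvs}")
    return min(cvs, 1.0)


def incident_points(category: IncidentCategory) -> int:
    """Severity points for an incident category (control 1 ... outbreak 4)."""
    try:
        category = IncidentCategory(category)
    except ValueError:
        valid = ", ".join(c.value for c in IncidentCategory)
        raise ValidationError(
            f"unknown incident category {category!r}; valid categories: {valid}"
        ) from None
    return _INCIDENT_POINTS[category]


def incident_category_level(incidents: Sequence[IncidentRecord]) -> float:
    """Mean severity points per incident, in [1, 4]."""
    if not incidents:
        raise MissingIndicator("incident_category", "no incidents to assess")
    total = sum(incident_points(r.incident_category) for r in incidents)
    return total / len(incidents)


def normalize_incident_level(level: float) -> float:
    """Bin the incident category level: [1, 1.75) -> 0.3; [1.75, 3.25) -> 0.7;
    [3.25, 4] -> 1.0."""
    if not (1.0 <= level <= 4.0):
        raise ValidationError(f"incident category level out of range [1,4]: {level}")
    if level < 1.75:
        return 0.3
    if level < 3.25:
        return 0.7
    return 1.0


def audit_metric(findings: Sequence[AuditFinding]) -> float:
    """Risk metric of the worst audit non-conformity: minor 0.3, major 0.7,
    critical 1.0."""
    if not findings:
        raise MissingIndicator("audit", "no audit data available")
    return max(_AUDIT_METRIC[AuditLevel(f.level)] for f in findings)


def normalize_lpi(lpi: float) -> float:
    """(5 - LPI) / 4: the best logistics score (5) maps to zero risk."""
    if not (1.0 <= lpi <= 5.0):
        raise ValidationError(f"lpi out of range [1,5]: {lpi}")
    return (5.0 - lpi) / 4.0


def normalize_gdp_per_capita(gdp_pc: float) -> float:
    """Bin GDP per capita (USD): < $1,046 -> 1.0 (low); $1,046-$12,695 -> 0.7;
    >= $12,696 -> 0.3 (high)."""
    if gdp_pc < 0:
        raise ValidationError(f"gdp_per_capita must be non-negative, got {gdp_pc}")
    if gdp_pc < 1046:
        return 1.0
    if gdp_pc < 12696:
        return 0.7
    return 0.3


def normalize_gdp_growth(growth: float) -> float:
    """Bin annual GDP growth (%): < 0 -> 1.0; [0, 2) -> 0.70; [2, 6) -> 0.42;
    >= 6 -> 0.125.

    Contracting economies carry the highest risk weight; strong growth
    the lowest.
    """
    if growth < 0:
        return 1.0
    if growth < 2:
        return 0.70
    if growth < 6:
        return 0.42
    return 0.125
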