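"""Built-in worked datasets and a synthetic input generator.

``table13_fixture`` returns the published ten-supplier benchmark set
(pre-normalized indicator vectors with the audit indicator missing
throughout, plus the expected scores and categories), which feeds the
aggregation stage directly.  ``vodka_example`` carries the
counterfeit-vodka worked example through the raw-notification path.
``generate_synthetic_inputs`` produces seeded random suppliers and
incident logs so the full pipeline is testable without any downloads.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .aggregation import IndicatorVector, SupplierCategory
from .errors import ValidationError
from .hazard import (
    HealthRisk,
    NotificationAttributes,
    NotificationReason,
    SignalCategory,
)
from .indicators import (
    AuditFinding,
    AuditLevel,
    CountryEconomics,
    IncidentCategory,
    IncidentRecord,
)
from .io import IncidentLogEntry, SupplierRecord


@dataclass(frozen=True)
class FixtureSet:
    """A set of suppliers with known indicator vectors and expected results."""

    suppliers: dict[str, IndicatorVector]
    expected_ors: dict[str, float]
    expected_category: dict[str, SupplierCategory]


# Ten benchmark suppliers: pre-normalized indicator vectors (audit data
# unavailable for all of them) and the published score/category row.
# Supplier H's published 46.6 differs from full-precision recomputation
# (46.5) by one ulp of the printed precision.
_TABLE13 = {
    #      hazard  cvs     incident  lpi    growth  per_capita   ors   category
    "A": ((1.00, 0.005, 0.7, 0.325, 0.70, 0.3), 67.1, SupplierCategory.MODERATE),
    "B": ((1.00, 0.05, 1.0, 0.300, 0.42, 0.3), 69.6, SupplierCategory.MODERATE),
    "C": ((1.00, 0.005, 0.7, 0.325, 0.42, 0.3), 65.6, SupplierCategory.MODERATE),
    "D": ((0.62, 0.004, 0.7, 0.275, 0.42, 0.3), 45.3, SupplierCategory.LOW),
    "E": ((1.00, 0.007, 0.7, 0.350, 0.70, 0.3), 67.3, SupplierCategory.MODERATE),
    "F": ((0.82, 0.0007, 0.7, 0.350, 0.42, 0.7), 58.3, SupplierCategory.MODERATE),
    "G": ((1.00, 0.0007, 0.7, 0.250, 0.70, 0.3), 66.6, SupplierCategory.MODERATE),
    "H": ((0.62, 0.004, 0.7, 0.225, 0.70, 0.3), 46.6, SupplierCategory.LOW),
    "I": ((1.00, 0.004, 0.7, 0.325, 0.42, 0.7), 67.7, SupplierCategory.MODERATE),
    "J": ((1.00, 0.0006, 0.7, 0.325, 0.42, 0.3), 65.5, SupplierCategory.MODERATE),
}


def table13_fixture() -> FixtureSet:
    """The ten-supplier benchmark set with expected scores and categories."""
    suppliers = {}
    expected_ors = {}
    expected_category = {}
    for sid, (vec, ors, cat) in _TABLE13.items():
        hazard, cvs, incident, lpi, growth, per_capita = vec
        suppliers[sid] = IndicatorVector(
            {
                "hazard_risk": hazard,
                "cvs": cvs,
                "incident_category": incident,
                "audit": None,
                "lpi": lpi,
                "gdp_growth": growth,
                "gdp_per_capita": per_capita,
            }
        )
        expected_ors[sid] = ors
        expected_category[sid] = cat
    return FixtureSet(
        suppliers=suppliers,
        expected_ors=expected_ors,
        expected_category=expected_category,
    )


@dataclass(frozen=True)
class VodkaExample:
    """The counterfeit-vodka worked example, from raw inputs to the report.

    A UK spirits supplier with one fraud notification (toxic isopropyl
    alcohol in counterfeit vodka): matrix relevant, a 3-point
    signal-category option, exceeded-limit reason, very serious health
    risk.  Five vodka incidents among 12,431 total in the window; no
    audit data; UK economics (LPI 3.7, GDP per capita $49,463.9, growth
    0.3%).
    """

    notification: NotificationAttributes
    commodity_incidents: int
    total_incidents: int
    incident_categories: tuple[IncidentCategory, ...]
    economics: CountryEconomics
    expected_hazard_points: int = 49
    expected_ors: float = 66.8
    expected_category: SupplierCategory = SupplierCategory.MODERATE


def vodka_example() -> VodkaExample:
    return VodkaExample(
        notification=NotificationAttributes(
            matrix_relevant=True,
            signal_category=SignalCategory.COMPLIANCE,  # a 3-point option
            notification_reason=NotificationReason.EXCEEDED_LIMIT,
            health_risk=HealthRisk.VERY_SERIOUS,
        ),
        commodity_incidents=5,
        total_incidents=12431,
        incident_categories=(IncidentCategory.FRAUD,),
        economics=CountryEconomics(lpi=3.7, gdp_per_capita=49463.9, gdp_growth=0.3),
    )


_COMMODITY_POOL = (
    "vodka",
    "onions",
    "ice cream",
    "baby food",
    "chicken meat",
    "olive oil",
    "cheese",
    "flour",
)

_DEFAULT_CATEGORY_PROBS = {
    IncidentCategory.CONTROL: 0.35,
    IncidentCategory.RECALL: 0.20,
    IncidentCategory.OUTBREAK: 0.05,
    IncidentCategory.FRAUD: 0.10,
    IncidentCategory.CONSUMER_COMPLAINT: 0.15,
    IncidentCategory.OTHER: 0.15,
}


def generate_synthetic_inputs(
    seed: int,
    n_suppliers: int = 10,
    n_incidents: int = 200,
    category_probabilities: Mapping[IncidentCategory, float] | None = None,
    as_of: dt.date = dt.date(2025, 1, 1),
) -> tuple[list[SupplierRecord], list[IncidentLogEntry]]:
    """Seeded random suppliers plus a shared market incident log.

    Incident dates are uniform over the 24 months before ``as_of`` so the
    12-month window filter is exercised on both sides of the boundary.
    Incident categories follow ``category_probabilities`` (default: a
    control-heavy mix resembling routine border sampling); hazard
    attributes are attached to roughly 70% of rows.  Economic values are
    drawn within their valid ranges; audit findings are present for about
    half the suppliers, mirroring restricted audit-data availability.
    Output is deterministic for a given seed.
    """
    if n_suppliers < 1 or n_incidents < 0:
        raise ValidationError("n_suppliers must be >= 1 and n_incidents >= 0")
    if category_probabilities is None:
        category_probabilities = _DEFAULT_CATEGORY_PROBS
    cats = [IncidentCategory(c) for c in category_probabilities]
    probs = np.asarray([category_probabilities[c] for c in category_probabilities], float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"category probabilities must be non-negative and sum to 1, got sum {probs.sum()}"
        )

    rng = np.random.default_rng(seed)
    span_days = 730  # 24 months
    signal_opts = list(SignalCategory)
    reason_opts = list(NotificationReason)
    health_opts = list(HealthRisk)

    entries: list[IncidentLogEntry] = []
    for _ in range(n_incidents):
        date = as_of - dt.timedelta(days=int(rng.integers(0, span_days)))
        commodity = _COMMODITY_POOL[int(rng.integers(0, len(_COMMODITY_POOL)))]
        category = cats[int(rng.choice(len(cats), p=probs))]
        record = IncidentRecord(date=date, commodity=commodity, incident_category=category)
        if rng.random() < 0.7:
            notification = NotificationAttributes(
                matrix_relevant=bool(rng.random() < 0.9),
                signal_category=signal_opts[int(rng.integers(0, len(signal_opts)))],
                notification_reason=reason_opts[int(rng.integers(0, len(reason_opts)))],
                health_risk=health_opts[int(rng.integers(0, len(health_opts)))],
            )
            entries.append(IncidentLogEntry(record=record, notification=notification))
        else:
            entries.append(IncidentLogEntry(record=record))

    suppliers: list[SupplierRecord] = []
    for i in range(n_suppliers):
        economics = CountryEconomics(
            lpi=float(np.round(rng.uniform(1.0, 5.0), 2)),
            gdp_per_capita=float(np.round(rng.uniform(500, 80000), 1)),
            gdp_growth=float(np.round(rng.uniform(-3.0, 8.0), 1)),
        )
        findings = []
        if rng.random() < 0.5:
            levels = list(AuditLevel)
            findings = [
                AuditFinding(level=levels[int(rng.integers(0, len(levels)))])
                for _ in range(int(rng.integers(1, 4)))
            ]
        suppliers.append(
            SupplierRecord(
                supplier_id=f"S{i + 1:03d}",
                country="synthetic",
                commodity=_COMMODITY_POOL[int(rng.integers(0, len(_COMMODITY_POOL)))],
                economics=economics,
                audit_findings=findings,
            )
        )
    return suppliers, entries
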