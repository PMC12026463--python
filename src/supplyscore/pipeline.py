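"""End-to-end supplier assessment composing the indicator sub-assessments.

Given a supplier record and an incident log, this computes each of the
seven indicators (marking those without data as missing), redistributes
the weights, and produces the risk report.  Incident-derived indicators
are restricted to the 12-month window before the assessment date.
"""

from __future__ import annotations

import datetime as dt
from typing import Sequence

from .aggregation import IndicatorVector, RiskReport, WeightConfig, overall_risk_score
from .errors import MissingIndicator
from .hazard import HazardFramework, DEFAULT_FRAMEWORK, aggregate_hazard
from .indicators import (
    audit_metric,
    compute_cvs,
    incident_category_level,
    normalize_cvs,
    normalize_gdp_growth,
    normalize_gdp_per_capita,
    normalize_incident_level,
    normalize_lpi,
    window_contains,
)
from .io import IncidentLogEntry, SupplierRecord


def _commodity_key(text: str) -> str:
    return text.strip().lower()


def assess_supplier(
    record: SupplierRecord,
    incidents: Sequence[IncidentLogEntry] | None = None,
    as_of: dt.date | None = None,
    weights: WeightConfig | None = None,
    hazard_policy: str = "worst_case",
    framework: HazardFramework = DEFAULT_FRAMEWORK,
) -> RiskReport:
    """Run the full seven-indicator assessment for one supplier.

    ``incidents`` is the market-wide incident log (defaults to the
    incidents carried on the record itself).  The supplier's own
    incidents are the log rows matching its commodity; they feed the
    hazard, CVS and incident-category indicators.  Audit and economic
    indicators come from the record.  Any indicator without data is
    marked missing and its weight redistributed.
    """
    if incidents is None:
        incidents = record.incidents
    if as_of is None:
        as_of = dt.date.today()

    windowed = [e for e in incidents if window_contains(e.record.date, as_of)]
    key = _commodity_key(record.commodity)
    own = [e for e in windowed if _commodity_key(e.record.commodity) == key]

    values: dict[str, float | None] = {}

    notifications = [e.notification for e in own if e.notification is not None]
    try:
        values["hazard_risk"] = aggregate_hazard(notifications, framework, hazard_policy).normalized
    except MissingIndicator:
        values["hazard_risk"] = None

    try:
        values["cvs"] = normalize_cvs(compute_cvs(len(own), len(windowed)))
    except MissingIndicator:
        values["cvs"] = None

    try:
        values["incident_category"] = normalize_incident_level(
            incident_category_level([e.record for e in own])
        )
    except MissingIndicator:
        values["incident_category"] = None

    try:
        values["audit"] = audit_metric(record.audit_findings)
    except MissingIndicator:
        values["audit"] = None

    econ = record.economics
    values["lpi"] = normalize_lpi(econ.lpi) if econ.lpi is not None else None
    values["gdp_per_capita"] = (
        normalize_gdp_per_capita(econ.gdp_per_capita)
        if econ.gdp_per_capita is not None
        else None
    )
    values["gdp_growth"] = (
        normalize_gdp_growth(econ.gdp_growth) if econ.gdp_growth is not None else None
    )

    return overall_risk_score(
        IndicatorVector(values), weights, supplier_id=record.supplier_id
    )
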