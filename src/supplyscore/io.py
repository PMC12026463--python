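"""Readers, writers and configuration for the supplier risk assessment.

Input formats are deliberately plain: supplier records as JSON objects,
incident logs as CSV, weight overrides as a flat YAML/JSON key-value
map.  Reports serialize to machine-readable JSON (full precision) or a
human-readable text table (one-decimal percentages).
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .aggregation import (
    DEFAULT_WEIGHTS,
    INDICATOR_IDS,
    RiskReport,
    SupplierCategory,
    WeightConfig,
)
from .errors import ValidationError
from .hazard import (
    HealthRisk,
    NotificationAttributes,
    NotificationReason,
    SignalCategory,
)
from .indicators import AuditFinding, AuditLevel, CountryEconomics, IncidentCategory, IncidentRecord

logger = logging.getLogger(__name__)

_KNOWN_RECORD_KEYS = {
    "supplier_id",
    "name",
    "country",
    "commodity",
    "economics",
    "audit_findings",
    "incidents",
    "incident_log",
}

_HAZARD_COLUMNS = ("signal_category", "notification_reason", "health_risk", "matrix_relevant")


@dataclass(frozen=True)
class IncidentLogEntry:
    """One incident-log row: the dated incident plus, when the hazard
    attribute columns are filled in, the scorable notification."""

    record: IncidentRecord
    notification: NotificationAttributes | None = None


@dataclass
class SupplierRecord:
    """A supplier under assessment and its locally supplied data."""

    supplier_id: str
    country: str
    commodity: str
    name: str | None = None
    economics: CountryEconomics = field(default_factory=CountryEconomics)
    audit_findings: list[AuditFinding] = field(default_factory=list)
    incidents: list[IncidentLogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.supplier_id:
            raise ValidationError("supplier_id must be non-empty")


def _parse_bool(value: Any, context: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "y"):
        return True
    if text in ("false", "0", "no", "n"):
        return False
    raise ValidationError(f"{context}: cannot interpret {value!r} as a boolean")


def _parse_incident_entry(row: dict[str, Any], context: str) -> IncidentLogEntry:
    try:
        date = pd.Timestamp(row["date"]).date()
    except (KeyError, ValueError, TypeError) as exc:
        raise ValidationError(f"{context}: unparseable or missing date ({exc})") from None
    commodity = str(row.get("commodity", "")).strip()
    if not commodity:
        raise ValidationError(f"{context}: commodity must be non-empty")
    try:
        category = IncidentCategory(str(row["incident_category"]).strip().lower())
    except (KeyError, ValueError):
        valid = ", ".join(c.value for c in IncidentCategory)
        raise ValidationError(
            f"{context}: incident_category {row.get('incident_category')!r} invalid; "
            f"valid categories: {valid}"
        ) from None
    record = IncidentRecord(date=date, commodity=commodity, incident_category=category)

    hazard_values = {c: row.get(c) for c in _HAZARD_COLUMNS}
    filled = {
        c: v
        for c, v in hazard_values.items()
        if v is not None and not (isinstance(v, float) and pd.isna(v)) and str(v).strip() != ""
    }
    if not filled:
        return IncidentLogEntry(record=record)
    missing = [c for c in _HAZARD_COLUMNS if c not in filled]
    if missing:
        raise ValidationError(
            f"{context}: partial hazard attributes; missing column(s) {missing}"
        )
    try:
        notification = NotificationAttributes(
            matrix_relevant=_parse_bool(filled["matrix_relevant"], context),
            signal_category=SignalCategory(str(filled["signal_category"]).strip().lower()),
            notification_reason=NotificationReason(
                str(filled["notification_reason"]).strip().lower()
            ),
            health_risk=HealthRisk(str(filled["health_risk"]).strip().lower()),
        )
    except ValueError as exc:
        raise ValidationError(f"{context}: invalid hazard attribute ({exc})") from None
    return IncidentLogEntry(record=record, notification=notification)


def read_incident_log(path: str | Path) -> list[IncidentLogEntry]:
    """Read an incident CSV (header: date,commodity,incident_category plus
    optional signal_category,notification_reason,health_risk,matrix_relevant)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"incident log not found: {path}")
    df = pd.read_csv(path, dtype=str)
    required = {"date", "commodity", "incident_category"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"incident log {path} missing required column(s): {sorted(missing)}"
        )
    entries = []
    for i, row in enumerate(df.to_dict(orient="records")):
        entries.append(_parse_incident_entry(row, f"{path.name} line {i + 2}"))
    return entries


def read_supplier_record(path: str | Path) -> SupplierRecord:
    """Read and validate a supplier record JSON file.

    Unknown keys are warned about and ignored; invariant violations
    (e.g. an LPI outside [1, 5]) raise :class:`ValidationError` naming
    the field.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"supplier record not found: {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(
            f"{path.name}: malformed JSON at line {exc.lineno}: {exc.msg}"
        ) from None
    if not isinstance(data, dict):
        raise ValidationError(f"{path.name}: supplier record must be a JSON object")

    unknown = set(data) - _KNOWN_RECORD_KEYS
    for key in sorted(unknown):
        logger.warning("%s: ignoring unknown key %r", path.name, key)

    for key in ("supplier_id", "country", "commodity"):
        if not str(data.get(key, "")).strip():
            raise ValidationError(f"{path.name}: field '{key}' is required and non-empty")

    econ_raw = data.get("economics", {})
    if not isinstance(econ_raw, dict):
        raise ValidationError(f"{path.name}: field 'economics' must be an object")
    for key in econ_raw:
        if key not in ("lpi", "gdp_per_capita", "gdp_growth"):
            logger.warning("%s: ignoring unknown economics key %r", path.name, key)
    economics = CountryEconomics(
        lpi=econ_raw.get("lpi"),
        gdp_per_capita=econ_raw.get("gdp_per_capita"),
        gdp_growth=econ_raw.get("gdp_growth"),
    )

    findings = []
    for j, item in enumerate(data.get("audit_findings", []) or []):
        level = item.get("level") if isinstance(item, dict) else item
        try:
            findings.append(AuditFinding(level=AuditLevel(str(level).strip().lower())))
        except ValueError:
            valid = ", ".join(l.value for l in AuditLevel)
            raise ValidationError(
                f"{path.name}: audit_findings[{j}] level {level!r} invalid; "
                f"valid levels: {valid}"
            ) from None

    entries: list[IncidentLogEntry] = []
    inline = data.get("incidents")
    if inline is not None:
        if not isinstance(inline, list):
            raise ValidationError(f"{path.name}: field 'incidents' must be a list")
        for j, row in enumerate(inline):
            entries.append(_parse_incident_entry(row, f"{path.name} incidents[{j}]"))
    log_ref = data.get("incident_log")
    if log_ref:
        entries.extend(read_incident_log(path.parent / log_ref))

    return SupplierRecord(
        supplier_id=str(data["supplier_id"]),
        name=data.get("name"),
        country=str(data["country"]),
        commodity=str(data["commodity"]),
        economics=economics,
        audit_findings=findings,
        incidents=entries,
    )


def read_weights_config(path: str | Path | None) -> WeightConfig:
    """Read a flat indicator-id -> percentage map (YAML or JSON syntax).

    With no path, the recommended default weights (50, 20, 10, 5, 5, 5, 5)
    apply.  Weights not summing to 100 are rejected with the offending sum.
    """
    if path is None:
        return WeightConfig(dict(DEFAULT_WEIGHTS))
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"weights config not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path.name}: malformed weights config: {exc}") from None
    if not isinstance(data, dict):
        raise ValidationError(f"{path.name}: weights config must be a key-value map")
    try:
        return WeightConfig({str(k): float(v) for k, v in data.items()})
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path.name}: non-numeric weight value ({exc})") from None


def report_to_dict(report: RiskReport) -> dict[str, Any]:
    return {
        "supplier_id": report.supplier_id,
        "overall_risk_score": report.overall_risk_score,
        "category": report.category.value,
        "missing_indicators": list(report.missing_indicators),
        "indicator_values": dict(report.indicator_values),
        "effective_weights": dict(report.effective_weights),
        "contributions": dict(report.contributions),
        "borderline": report.is_borderline(),
    }


def report_from_json(text: str) -> RiskReport:
    """Reconstruct a :class:`RiskReport` from its JSON serialization."""
    data = json.loads(text)
    return RiskReport(
        supplier_id=data["supplier_id"],
        effective_weights=dict(data["effective_weights"]),
        contributions=dict(data["contributions"]),
        overall_risk_score=data["overall_risk_score"],
        category=SupplierCategory(data["category"]),
        missing_indicators=list(data["missing_indicators"]),
        indicator_values=dict(data["indicator_values"]),
    )


def write_report(report: RiskReport, format: str = "text", borderline_margin: float = 2.0) -> str:
    """Serialize a risk report.

    ``json`` keeps full precision and round-trips losslessly through
    :func:`report_from_json`; ``text`` is a human table with the ORS at
    one decimal, per-indicator contributions, a notice for missing
    indicators, and a human-review caveat when the score falls within
    ``borderline_margin`` points of a category boundary.
    """
    if format == "json":
        return json.dumps(report_to_dict(report), indent=2)
    if format != "text":
        raise ValidationError(f"unknown report format {format!r}; use 'json' or 'text'")

    lines = []
    title = f"Supplier risk assessment: {report.supplier_id}" if report.supplier_id else "Supplier risk assessment"
    lines.append(title)
    lines.append("=" * len(title))
    lines.append(f"{'Indicator':<20}{'Value':>8}{'Weight':>9}{'Contribution':>14}")
    lines.append("-" * 51)
    for ind in INDICATOR_IDS:
        if ind in report.indicator_values:
            lines.append(
                f"{ind:<20}{report.indicator_values[ind]:>8.4f}"
                f"{report.effective_weights[ind] * 100:>8.2f}%"
                f"{report.contributions[ind]:>14.4f}"
            )
        else:
            lines.append(f"{ind:<20}{'--':>8}{'--':>9}{'(missing)':>14}")
    lines.append("-" * 51)
    lines.append(f"Overall risk score: {report.overall_risk_score:.1f}%")
    lines.append(f"Risk category:      {report.category.value}")
    if report.missing_indicators:
        lines.append(
            "Note: no data for "
            + ", ".join(report.missing_indicators)
            + "; weight redistributed over the remaining indicators."
        )
    if report.is_borderline(borderline_margin):
        lines.append(
            f"CAUTION: score within {borderline_margin:g} points of a category "
            "boundary; human review of the underlying data is recommended."
        )
    return "\n".join(lines) + "\n"
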