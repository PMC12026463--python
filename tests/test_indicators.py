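"""Indicators 2-7: window selection, CVS, incident level, audit, economics."""

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from supplyscore import (
    AuditFinding,
    AuditLevel,
    CountryEconomics,
    IncidentCategory,
    IncidentRecord,
    MissingIndicator,
    ValidationError,
    audit_metric,
    compute_cvs,
    incident_category_level,
    incident_points,
    normalize_cvs,
    normalize_gdp_growth,
    normalize_gdp_per_capita,
    normalize_incident_level,
    normalize_lpi,
    select_window,
)

AS_OF = dt.date(2024, 12, 31)


def rec(date, commodity="vodka", category=IncidentCategory.CONTROL):
    return IncidentRecord(date=date, commodity=commodity, incident_category=category)


class TestSelectWindow:
    def test_half_open_twelve_month_window(self):
        inside = rec(dt.date(2024, 2, 1))       # 11 months before
        boundary = rec(dt.date(2023, 12, 31))   # exactly 12 months before
        outside = rec(dt.date(2023, 11, 30))    # 13 months before
        today = rec(AS_OF)
        future = rec(dt.date(2025, 1, 1))
        got = select_window([inside, boundary, outside, today, future], AS_OF)
        assert got == [inside, today]

    def test_matches_brute_force_day_filter(self):
        """Oracle: explicit day-by-day filter over a 2-year span of records."""
        start = dt.date(2023, 1, 1)
        records = [rec(start + dt.timedelta(days=i * 13)) for i in range(60)]
        window_start = dt.date(2023, 12, 31)  # as_of minus 12 calendar months
        expected = [r for r in records if window_start < r.date <= AS_OF]
        assert select_window(records, AS_OF) == expected


class TestCVS:
    def test_vodka_worked_example(self):
        assert compute_cvs(5, 12431) == pytest.approx(0.04, abs=0.005)
        assert round(compute_cvs(5, 12431), 2) == 0.04

    def test_zero_commodity_incidents(self):
        assert compute_cvs(0, 12431) == 0.0

    def test_small_fraction(self):
        assert compute_cvs(1, 13000) == pytest.approx(0.00769, rel=1e-3)

    def test_no_incidents_signals_missing(self):
        with pytest.raises(MissingIndicator):
            compute_cvs(0, 0)

    def test_commodity_cannot_exceed_total(self):
        with pytest.raises(ValidationError):
            compute_cvs(10, 5)

    @pytest.mark.parametrize("cvs, expected", [(0.04, 0.04), (3.8, 1.0), (0.0, 0.0), (1.0, 1.0)])
    def test_normalize_uses_percentage_numeral_with_clamp(self, cvs, expected):
        assert normalize_cvs(cvs) == expected

    def test_normalize_rejects_negative(self):
        with pytest.raises(ValidationError):
            normalize_cvs(-0.1)


class TestIncidentLevel:
    @pytest.mark.parametrize(
        "category, expected",
        [
            (IncidentCategory.CONTROL, 1),
            (IncidentCategory.RECALL, 3),
            (IncidentCategory.OUTBREAK, 4),
            (IncidentCategory.FRAUD, 3),
            (IncidentCategory.CONSUMER_COMPLAINT, 1),
            (IncidentCategory.OTHER, 2),
        ],
    )
    def test_incident_points(self, category, expected):
        assert incident_points(category) == expected

    def test_unknown_category_error_lists_valid_labels(self):
        with pytest.raises(ValidationError, match="outbreak"):
            incident_points("explosion")

    def test_mixed_worked_example(self):
        """3 recalls + 2 outbreaks + 1 control: (9 + 8 + 1) / 6 = 3."""
        incidents = (
            [rec(AS_OF, category=IncidentCategory.RECALL)] * 3
            + [rec(AS_OF, category=IncidentCategory.OUTBREAK)] * 2
            + [rec(AS_OF, category=IncidentCategory.CONTROL)]
        )
        assert incident_category_level(incidents) == 3.0

    def test_single_fraud(self):
        assert incident_category_level([rec(AS_OF, category=IncidentCategory.FRAUD)]) == 3.0

    def test_all_controls(self):
        assert incident_category_level([rec(AS_OF)] * 4) == 1.0

    def test_empty_signals_missing(self):
        with pytest.raises(MissingIndicator):
            incident_category_level([])

    @given(st.lists(st.sampled_from(list(IncidentCategory)), min_size=1, max_size=30))
    @settings(deadline=None)
    def test_level_bounded_and_matches_brute_force_mean(self, categories):
        points = {"control": 1, "recall": 3, "outbreak": 4, "fraud": 3,
                  "consumer_complaint": 1, "other": 2}
        incidents = [rec(AS_OF, category=c) for c in categories]
        level = incident_category_level(incidents)
        expected = sum(points[c.value] for c in categories) / len(categories)
        assert level == pytest.approx(expected)
        assert 1.0 <= level <= 4.0

    @pytest.mark.parametrize(
        "level, expected",
        [(3.0, 0.7), (4.0, 1.0), (1.0, 0.3), (1.74, 0.3), (1.75, 0.7), (3.24, 0.7), (3.25, 1.0)],
    )
    def test_normalize_incident_level_bins(self, level, expected):
        assert normalize_incident_level(level) == expected

    def test_normalize_incident_level_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            normalize_incident_level(0.5)
        with pytest.raises(ValidationError):
            normalize_incident_level(4.5)


class TestAudit:
    @pytest.mark.parametrize(
        "levels, expected",
        [
            ([AuditLevel.MINOR], 0.3),
            ([AuditLevel.CRITICAL], 1.0),
            ([AuditLevel.MINOR, AuditLevel.MAJOR], 0.7),
            ([AuditLevel.MAJOR, AuditLevel.MINOR, AuditLevel.CRITICAL], 1.0),
        ],
    )
    def test_worst_finding_rule(self, levels, expected):
        findings = [AuditFinding(level=l) for l in levels]
        assert audit_metric(findings) == expected
        # oracle: max over individually mapped findings
        assert audit_metric(findings) == max(audit_metric([f]) for f in findings)

    def test_no_audit_data_signals_missing(self):
        with pytest.raises(MissingIndicator):
            audit_metric([])


class TestEconomics:
    @pytest.mark.parametrize("lpi, expected", [(3.7, 0.325), (5.0, 0.0), (1.0, 1.0)])
    def test_normalize_lpi(self, lpi, expected):
        assert normalize_lpi(lpi) == pytest.approx(expected)

    def test_lpi_out_of_range(self):
        with pytest.raises(ValidationError, match=r"lpi out of range \[1,5\]"):
            normalize_lpi(7)

    @pytest.mark.parametrize(
        "gdp, expected",
        [(49463.9, 0.3), (1045, 1.0), (5000, 0.7), (0, 1.0), (1046, 0.7), (12696, 0.3), (12695, 0.7)],
    )
    def test_normalize_gdp_per_capita(self, gdp, expected):
        assert normalize_gdp_per_capita(gdp) == expected

    @pytest.mark.parametrize(
        "growth, expected",
        [(0.3, 0.70), (-0.3, 1.0), (6.5, 0.125), (0.0, 0.70), (2.0, 0.42), (5.5, 0.42), (6.0, 0.125)],
    )
    def test_normalize_gdp_growth(self, growth, expected):
        assert normalize_gdp_growth(growth) == expected

    @given(st.floats(min_value=-50, max_value=50, allow_nan=False))
    @settings(deadline=None)
    def test_growth_bins_partition_and_monotone(self, g):
        v = normalize_gdp_growth(g)
        assert v in (0.125, 0.42, 0.70, 1.0)
        assert normalize_gdp_growth(g + 0.5) <= v

    @given(st.floats(min_value=0, max_value=200000, allow_nan=False))
    @settings(deadline=None)
    def test_gdp_pc_bins_partition_and_monotone(self, g):
        v = normalize_gdp_per_capita(g)
        assert v in (0.3, 0.7, 1.0)
        assert normalize_gdp_per_capita(g + 100) <= v

    @given(st.floats(min_value=1, max_value=5, allow_nan=False))
    @settings(deadline=None)
    def test_lpi_strictly_decreasing_and_in_unit_interval(self, lpi):
        v = normalize_lpi(lpi)
        assert 0.0 <= v <= 1.0
        if lpi + 0.1 <= 5:
            assert normalize_lpi(lpi + 0.1) < v

    def test_country_economics_validates_lpi(self):
        with pytest.raises(ValidationError, match="lpi out of range"):
            CountryEconomics(lpi=7)
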