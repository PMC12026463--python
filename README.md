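# supplyscore

Quantitative food-safety supplier risk scoring.

Food businesses must judge, before and during procurement, how likely a
supplier is to ship unsafe goods. `supplyscore` implements a composite
scoring scheme for that judgement: it assesses a supplier through seven
indicators, normalizes each to a common [0, 1] risk scale, and combines
them into an **overall risk score (ORS)** — a percentage that places the
supplier into a *low* / *moderate* / *risky* band. It is aimed at
quality-assurance and sourcing teams who hold incident-notification logs
(RASFF-style), occasional audit reports, and public country-level
economic figures, and want a reproducible, configurable ranking of their
suppliers.

## The scoring model

The ORS is a weighted sum of seven normalized indicators
*I*₁…*I*₇ ∈ [0, 1] with fractional weights *W*ᵢ:

```
ORS = (I₁W₁ + I₂W₂ + I₃W₃ + I₄W₄ + I₅W₅ + I₆W₆ + I₇W₇) × 100
```

| # | Indicator | Default weight | Normalization |
|---|-----------|---------------:|---------------|
| 1 | Hazard risk of incident notifications | 50% | two-level weighted points / 50 |
| 2 | Commodity vulnerability score (CVS) | 20% | percentage numeral, clamped at 1 |
| 3 | Incident category level | 10% | mean severity points binned to 0.3 / 0.7 / 1.0 |
| 4 | Audit performance | 5% | worst finding: minor 0.3, major 0.7, critical 1.0 |
| 5 | Logistics Performance Index (LPI) | 5% | (5 − LPI) / 4 |
| 6 | GDP per capita | 5% | binned to 0.3 / 0.7 / 1.0 |
| 7 | GDP growth | 5% | binned to 0.125 / 0.42 / 0.70 / 1.0 |

The **hazard risk** of a single notification is Σᵢ *R*ᵢ·*P*ᵢ over four
criteria — matrix relevance (weight 1), signal category (1), reason of
notification (2), health risk (6) — where *P*ᵢ are the points of the
selected option. A relevant notification scores between 27 and 50
points; the score is binned (≤31 negligible, 32–37 low, 38–43 moderate,
≥44 high) and divided by 50.

The **CVS** is the share of all incidents in the trailing 12 calendar
months attributable to the supplier's commodity, as a percentage; the
percentage numeral itself is the [0, 1] indicator (0.04% → 0.04),
clamped at 1.

When an indicator has no data (audit reports are frequently
confidential), its weight is **redistributed proportionally** over the
remaining indicators — each remaining weight is scaled by
100 / (100 − Σ missing weights) — so effective weights always sum to
100%. A missing indicator is never scored as 0, since 0 is a legal
minimal-risk value (a perfect LPI of 5 normalizes to 0).

Finally the ORS is banded: below 50% *low*, 50–70% *moderate*, 70% and
above *risky*. Scores within 2 points of a band boundary are flagged
for human review.

## Worked example

A UK spirits supplier with one food-fraud notification (counterfeit
vodka containing toxic isopropyl alcohol): the notification is matrix
relevant, a compliance signal (3 points), an exceeded-limit reason
(6 points) and a very serious health risk (4 points), so the hazard
score is 1×10 + 1×3 + 2×6 + 6×4 = **49 points** (high risk, normalized
0.98). Five vodka incidents among 12,431 in the last year give a CVS of
0.04%; one fraud incident gives incident level 3/1 = 3 → 0.7; no audit
data; UK economics give LPI (5 − 3.7)/4 = 0.325, GDP per capita
$49,463.9 → 0.3, GDP growth 0.3% → 0.7.

```python
from supplyscore import overall_risk_score, write_report

report = overall_risk_score(
    {"hazard_risk": 0.98, "cvs": 0.04, "incident_category": 0.7,
     "audit": None, "lpi": 0.325, "gdp_per_capita": 0.3, "gdp_growth": 0.7},
    supplier_id="UK-VODKA-01",
)
print(write_report(report, "text"))
```

```
Supplier risk assessment: UK-VODKA-01
=====================================
Indicator              Value   Weight  Contribution
---------------------------------------------------
hazard_risk           0.9800   52.63%        0.5158
cvs                   0.0400   21.05%        0.0084
incident_category     0.7000   10.53%        0.0737
audit                     --       --     (missing)
lpi                   0.3250    5.26%        0.0171
gdp_per_capita        0.3000    5.26%        0.0158
gdp_growth            0.7000    5.26%        0.0368
---------------------------------------------------
Overall risk score: 66.8%
Risk category:      moderate
Note: no data for audit; weight redistributed over the remaining indicators.
```

The missing audit indicator's 5% was redistributed (scaling factor
100/95 = 1.0526, so the hazard weight becomes 52.63%), and the weighted
sum gives an ORS of 66.8% — a moderate-risk supplier.

The same assessment runs end to end from files:

```sh
supplyscore score --supplier uk_vodka.json --incidents incidents.csv \
    --as-of 2024-12-31 --format json
```

where `uk_vodka.json` holds the supplier record (id, country, commodity,
economics, optional audit findings) and `incidents.csv` the dated
incident log (`date,commodity,incident_category` plus optional hazard
attribute columns). `supplyscore score-batch --dir DIR` scores a
directory of records; `supplyscore fixtures table13` emits the built-in
ten-supplier benchmark set. Custom weights go in a flat YAML/JSON map
passed with `--weights` and must sum to 100.

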