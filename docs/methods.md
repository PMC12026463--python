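# Methods

This note documents the scoring model implemented by `supplyscore`, the
conventions it adopts where the published classification tables are
ambiguous, what the synthetic data generator does and does not emulate,
and the package's known limitations.

## Model and assumptions

A supplier's risk is modelled as a convex combination of seven
indicator risks, each normalized to [0, 1] with higher = riskier,
scaled to a percentage:

ORS = Σᵢ Iᵢ·Wᵢ × 100,  Σᵢ Wᵢ = 1.

The model is purely additive: indicators are assumed independent and
substitutable at the rate set by the weights. No interaction terms, no
learning — the weights are expert-set configuration, defaulting to
50 / 20 / 10 / 5 / 5 / 5 / 5 percent for hazard risk, CVS, incident
category, audit, LPI, GDP per capita and GDP growth respectively.
Weight configurations must sum to 100 (tolerance 1e-9) with no
negative entries.

### Hazard risk (indicator 1)

One notification is scored as Σᵢ Rᵢ·Pᵢ over four criteria with
first-level weights R = (1, 1, 2, 6) for matrix relevance, signal
category, reason of notification and health risk, and second-level
option points: relevance addressed 10; safety 4, compliance 3, public
perception 3; exceeded limit 6, new recommendation 4; health risk
limited 1 / moderate 2 / serious 3 / very serious 4. A relevant
notification therefore scores in [27, 50] (verified by exhaustive
enumeration of the 24 option combinations). Categories: ≤31
negligible, 32–37 low, 38–43 moderate, ≥44 high — 43 is assigned to
*moderate*; the source tables print the 43 boundary in both the
moderate and high rows, and the contiguous-partition reading consistent
with the summary table is moderate up to 43, high from 44.
Normalization divides by the framework maximum (50 by default; a custom
framework normalizes by its own maximum).

Notifications not addressing the matrix of interest are *skipped*
(logged), not scored with zero relevance points: the scheme only
defines scores for relevant notifications. Scoring one directly is an
error; at the aggregation level an all-irrelevant (or empty) set marks
the indicator missing.

Combining several notifications into one hazard indicator is not part
of the published scheme, which scores a single notification. The
package defaults to **worst-case** (the maximal raw score), on the
precautionary argument that one severe incident dominates a supplier's
hazard history; a **mean** policy (arithmetic mean of normalized
scores, category from mean × 50) is available for users who prefer a
central tendency.

### Commodity vulnerability score (indicator 2)

CVS = (incidents for the commodity / total incidents) × 100 over the
trailing 12 calendar months. The window is a full year to absorb
seasonality, computed as the half-open interval
(as_of − 12 months, as_of] with a caller-supplied assessment date so
results are reproducible; a record dated exactly 12 months before the
assessment date falls outside. The percentage *numeral* is used
directly as the [0, 1] indicator (0.04% contributes 0.04) and clamped
at 1.0 for commodities exceeding 1% of all incidents. The alternative
convention — using the raw fraction — appears once in the source
material's minimum-value table (1/13,000 = 7.69×10⁻⁵); that verbatim
value is retained in the minimum-ORS calculation, where the two
conventions are numerically indistinguishable at the printed precision.
Whether incident counts are global or market-scoped is the caller's
choice; the pipeline counts within whatever log it is given.

### Incident category level (indicator 3)

Mean severity points per incident — control 1, consumer complaint 1,
other 2, recall 3, fraud 3, outbreak 4 — bounded in [1, 4]. Binning:
[1, 1.75) → 0.3, [1.75, 3.25) → 0.7, [3.25, 4] → 1.0. The source
prints two conflicting bin tables; the one adopted here is the detailed
table, which is the only one consistent with the worked example
(level 3 → 0.7) and with a level of 4 being attainable at all. Shared
boundary values are assigned upward (1.75 → 0.7, 3.25 → 1.0).

### Audit performance (indicator 4)

Worst non-conformity of the supplier's audit findings: minor 0.3,
major 0.7, critical 1.0. The worst-finding rule is this package's
convention for audits reporting several findings (the scheme maps one
audit to one level). Audit data are frequently confidential; an empty
finding list marks the indicator missing.

### Country economics (indicators 5–7)

- LPI ∈ [1, 5], normalized (5 − LPI)/4 — best logistics → 0 risk.
- GDP per capita (USD): < $1,046 → 1.0, $1,046–$12,695 → 0.7,
  ≥ $12,696 → 0.3. The published bands leave the open interval
  ($1,045, $1,046) undefined for non-integer inputs; the moderate band
  is extended down to 1046 exclusive.
- GDP growth (% p.a.): < 0 → 1.0, [0, 2) → 0.70, [2, 6) → 0.42,
  ≥ 6 → 0.125. The published bands double-cover negatives ("low ≤ 2"
  vs "negative < 0") and leave (5, 6) unassigned; negative takes
  precedence below zero and the moderate band is extended to [2, 6),
  giving a contiguous partition that preserves all worked examples.

All three values are caller-supplied (World Bank figures in practice);
the package does no retrieval.

## Missing indicators and weight redistribution

A missing indicator's weight is redistributed proportionally: each
remaining percentage weight is divided by the sum of remaining weights,
yielding fractions that sum to 1 and preserve pairwise ratios.
Missingness is explicit (None), never encoded as 0. With the default
weights and audit missing the scaling factor is 100/95 = 1.0526
(hazard 50% → 52.63%). Scoring requires at least one present indicator
with positive remaining weight.

## Categorization and numerical choices

ORS bands: < 50 low, [50, 70) moderate, ≥ 70 risky. Boundary scores
take the worse band, the precautionary reading. Under default weights
and all indicators at their minimum the ORS floor is 33.63%; custom
weights can drive scores below that floor, and such scores are still
*low* rather than errors, since the floor is a property of the default
weights only.

All arithmetic is full-precision; rounding to one decimal happens only
at presentation. This matters for the worked example: the source
prints an intermediate 66.79% obtained from 4-digit-rounded weights,
while full precision gives 66.76% — both round to the headline 66.8%.
In the ten-supplier benchmark, nine scores match the printed row
exactly at one decimal; supplier H recomputes to 46.5 against a printed
46.6 (intermediate rounding upstream), so the regression test allows
±0.1.

The text report flags scores within 2 percentage points of a band
boundary for human review; the margin is configurable and
operationalizes the recommendation that borderline classifications be
judged by a person.

## Synthetic data generator

`generate_synthetic_inputs` produces seeded supplier records and a
shared market incident log for pipeline testing: incident dates uniform
over the 24 months before the assessment date (so the 12-month window
filter is exercised on both sides), categories drawn from a
configurable distribution defaulting to a control-heavy mix resembling
routine border sampling, hazard attributes attached to ~70% of rows
with 90% matrix relevance, economics uniform within their valid ranges,
and audit findings for about half the suppliers (mirroring restricted
audit availability). All randomness flows through one
`numpy.random.default_rng(seed)`; no global state.

The generator emulates the *shape* of real incident logs, not their
statistics: real RASFF-style feeds have heavy-tailed commodity
frequencies, temporal clustering (outbreaks), and correlated attributes
(outbreaks skew toward serious health risks), none of which are
modelled. Passing tests on synthetic data therefore demonstrate
pipeline correctness — windowing, indicator wiring, missing-data
handling, determinism — not calibration of the scoring scheme against
real-world supplier outcomes, which the scheme's fixed points and
weights do not attempt.

The built-in benchmark set stores the ten suppliers' *pre-normalized*
indicator vectors (their underlying notifications are not published),
so it feeds the aggregation stage directly; the vodka example
additionally exercises the raw-notification path end to end.

## Problem sizes

Everything here is desk-scale: single notifications, incident logs of
10²–10⁴ rows, ten-supplier batches. The full test suite and the
acceptance script each run in seconds on one CPU.

## Limitations

- The weights are recommendations, not fitted parameters; the scheme
  has no probabilistic interpretation and the ORS is an index, not a
  probability of a safety event.
- Indicators enter additively; a supplier can offset a severe hazard
  history with benign economics, which may be undesirable — hence the
  borderline-review flag.
- A notification whose reason is neither "exceeded limit" nor "new
  recommendation" cannot be scored and is an error; the framework
  defines no points for other reasons (the option maps are
  configuration, so users can extend them).
- CVS depends on the scope of the incident log supplied; the package
  does not define or fetch a canonical market-wide log.
- No text mining: notifications must arrive pre-labelled with their
  categorical attributes.
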