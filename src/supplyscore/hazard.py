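"""Hazard-risk scoring of individual incident notifications (indicator 1 of 7).

A notification is scored under a two-level weighting framework: each of
four criteria (relevance of the matrix, signal category, reason of
notification, health risk) carries a first-level weight R_i, and the
option selected within the criterion carries second-level points P_i.
The hazard score is sum(R_i * P_i); under the default framework a
relevant notification scores between 27 and 50 points.  The score is
binned into four hazard categories and normalized by the framework
maximum (50) for use in the overall risk score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import MissingIndicator, ValidationError

logger = logging.getLogger(__name__)


class SignalCategory(str, Enum):
    SAFETY = "safety"
    COMPLIANCE = "compliance"
    PUBLIC_PERCEPTION = "public_perception"


class NotificationReason(str, Enum):
    EXCEEDED_LIMIT = "exceeded_limit"
    NEW_RECOMMENDATION = "new_recommendation"


class HealthRisk(str, Enum):
    LIMITED = "limited"
    MODERATE = "moderate"
    SERIOUS = "serious"
    VERY_SERIOUS = "very_serious"


class HazardCategory(str, Enum):
    NEGLIGIBLE = "negligible"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


CRITERIA = ("relevance", "signal_category", "notification_reason", "health_risk")


@dataclass(frozen=True)
class NotificationAttributes:
    """The four categorical attributes of a scorable incident notification."""

    matrix_relevant: bool
    signal_category: SignalCategory | None
    notification_reason: NotificationReason | None
    health_risk: HealthRisk | None


_DEFAULT_FIRST_LEVEL = {
    "relevance": 1,
    "signal_category": 1,
    "notification_reason": 2,
    "health_risk": 6,
}

_DEFAULT_SECOND_LEVEL = {
    "relevance": {"addressed": 10},
    "signal_category": {
        SignalCategory.SAFETY: 4,
        SignalCategory.COMPLIANCE: 3,
        SignalCategory.PUBLIC_PERCEPTION: 3,
    },
    "notification_reason": {
        NotificationReason.EXCEEDED_LIMIT: 6,
        NotificationReason.NEW_RECOMMENDATION: 4,
    },
    "health_risk": {
        HealthRisk.LIMITED: 1,
        HealthRisk.MODERATE: 2,
        HealthRisk.SERIOUS: 3,
        HealthRisk.VERY_SERIOUS: 4,
    },
}


@dataclass(frozen=True)
class HazardFramework:
    """Two-level weighting framework for notification scoring.

    ``first_level_weights`` maps each criterion to its weight R_i;
    ``second_level_points`` maps each criterion's options to points P_i.
    Defaults encode the standard framework (weights 1, 1, 2, 6; relevance
    addressed = 10; safety 4 / compliance 3 / public perception 3;
    exceeded limit 6 / new recommendation 4; health risk 1-4).  Both maps
    are configuration: overriding them rescales the attainable range, and
    normalization always divides by the framework's own maximum.
    """

    first_level_weights: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_FIRST_LEVEL)
    )
    second_level_points: Mapping[str, Mapping] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SECOND_LEVEL.items()}
    )

    def __post_init__(self) -> None:
        for crit in CRITERIA:
            if crit not in self.first_level_weights:
                raise ValidationError(f"framework missing first-level weight for '{crit}'")
            w = self.first_level_weights[crit]
            if not isinstance(w, int) or w <= 0:
                raise ValidationError(
                    f"first-level weight for '{crit}' must be a positive integer, got {w!r}"
                )
            opts = self.second_level_points.get(crit)
            if not opts:
                raise ValidationError(f"framework missing second-level points for '{crit}'")
            for opt, p in opts.items():
                if not isinstance(p, int) or p <= 0:
                    raise ValidationError(
                        f"second-level points for '{crit}' option {opt!r} must be a "
                        f"positive integer, got {p!r}"
                    )

    @property
    def max_points(self) -> int:
        """Maximum attainable score: best option per criterion times its weight."""
        return sum(
            self.first_level_weights[c] * max(self.second_level_points[c].values())
            for c in CRITERIA
        )

    @property
    def min_points(self) -> int:
        """Minimum attainable score for a relevant notification."""
        return sum(
            self.first_level_weights[c] * min(self.second_level_points[c].values())
            for c in CRITERIA
        )


DEFAULT_FRAMEWORK = HazardFramework()


@dataclass(frozen=True)
class HazardAssessment:
    """Scored hazard for one notification or a combined set of them."""

    raw_points: float
    category: HazardCategory
    normalized: float


def score_notification(
    attrs: NotificationAttributes, framework: HazardFramework = DEFAULT_FRAMEWORK
) -> int:
    """Weighted point total sum(R_i * P_i) over the four criteria.

    Raises ValidationError for an irrelevant notification (matrix not
    addressed — the framework never scores those) or for a missing
    attribute, naming the criterion.
    """
    if not attrs.matrix_relevant:
        raise ValidationError(
            "notification is not relevant to product of interest; hazard scoring "
            "applies only to notifications addressing the matrix under assessment"
        )
    selected = {
        "relevance": "addressed",
        "signal_category": attrs.signal_category,
        "notification_reason": attrs.notification_reason,
        "health_risk": attrs.health_risk,
    }
    total = 0
    for crit in CRITERIA:
        option = selected[crit]
        if option is None:
            raise ValidationError(f"notification attribute '{crit}' is missing")
        opts = framework.second_level_points[crit]
        if option not in opts:
            valid = ", ".join(str(getattr(o, "value", o)) for o in opts)
            raise ValidationError(
                f"unknown option {getattr(option, 'value', option)!r} for criterion "
                f"'{crit}'; valid options: {valid}"
            )
        total += framework.first_level_weights[crit] * opts[option]
    return total


def categorize_hazard(points: float) -> HazardCategory:
    """Bin a hazard point total: <=31 negligible, 32-37 low, 38-43 moderate, >=44 high."""
    if points < 0:
        raise ValidationError(f"hazard points must be non-negative, got {points}")
    if points <= 31:
        return HazardCategory.NEGLIGIBLE
    if points <= 37:
        return HazardCategory.LOW
    if points <= 43:
        return HazardCategory.MODERATE
    return HazardCategory.HIGH


def normalize_hazard(
    points: float, framework: HazardFramework = DEFAULT_FRAMEWORK
) -> float:
    """Scale a hazard point total to [0, 1] by the framework maximum (default 50)."""
    if points < 0:
        raise ValidationError(f"hazard points must be non-negative, got {points}")
    maximum = framework.max_points
    if points > maximum:
        raise ValidationError(
            f"hazard points {points} exceed the framework maximum of {maximum}"
        )
    return points / maximum


def aggregate_hazard(
    notifications: Iterable[NotificationAttributes],
    framework: HazardFramework = DEFAULT_FRAMEWORK,
    policy: str = "worst_case",
) -> HazardAssessment:
    """Combine several notifications into one hazard assessment.

    ``worst_case`` (default) keeps the notification with the maximal raw
    score; ``mean`` averages the normalized per-notification values and
    derives the category from mean * framework maximum.  Notifications
    not addressing the matrix of interest are skipped (logged, not
    errors).  With no relevant notification the hazard indicator is
    signalled as missing.
    """
    if policy not in ("worst_case", "mean"):
        raise ValidationError(f"unknown hazard aggregation policy {policy!r}")
    scores: list[int] = []
    skipped = 0
    for attrs in notifications:
        if not attrs.matrix_relevant:
            skipped += 1
            continue
        scores.append(score_notification(attrs, framework))
    if skipped:
        logger.info("skipped %d notification(s) not relevant to the matrix", skipped)
    if not scores:
        raise MissingIndicator("hazard_risk", "no relevant notifications to score")
    if policy == "worst_case":
        raw: float = max(scores)
    else:
        raw = sum(normalize_hazard(s, framework) for s in scores) / len(scores)
        raw *= framework.max_points
    return HazardAssessment(
        raw_points=raw,
        category=categorize_hazard(raw),
        normalized=normalize_hazard(raw, framework),
    )


def enumerate_scores(
    framework: HazardFramework = DEFAULT_FRAMEWORK,
) -> list[int]:
    """Scores of every option combination for a relevant notification.

    Exhaustive enumeration over one option per criterion (relevance fixed
    to "addressed"); 1 x 3 x 2 x 4 = 24 combinations under the default
    framework.  Used to establish the attainable score range.
    """
    scores: list[int] = []
    for sig in framework.second_level_points["signal_category"]:
        for reason in framework.second_level_points["notification_reason"]:
            for hr in framework.second_level_points["health_risk"]:
                attrs = NotificationAttributes(
                    matrix_relevant=True,
                    signal_category=sig,
                    notification_reason=reason,
                    health_risk=hr,
                )
                scores.append(score_notification(attrs, framework))
    return scores
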