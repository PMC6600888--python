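"""Modified AUDIT-C scoring and category-midpoint risk estimation.

The screening instrument modifies the three AUDIT-C consumption items for a
context of intermittent, heavy, shared drinking:

* AUDIT-1m — frequency of any drinking, asked with colloquial wording on a
  five-level ordinal scale; past-year drinkers are never offered "Never".
* AUDIT-2m — usual quantity per occasion, *derived* from the Finnish-method
  drinks-per-occasion estimate and recoded into the standard AUDIT-2
  categories (0: 1-2 drinks, 1: 3-4, 2: 5-6, 3: 7-9, 4: 10+).
* AUDIT-3mV — frequency of drinking more than four standard drinks (shown
  visually as five standard drinks, ~50 g ethanol) on one occasion.

Each item scores 0-4; the AUDIT-Cm total (0-12) flags risk at >= 3 for women
and >= 4 for men.  Item subsets are converted back to consumption scales via
category midpoints (so weekly drinking is 0.14 occasions per day) to estimate
short-term risk (>4 drinks on an occasion) and long-term risk (average >2
drinks/day) from the shortened instruments alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping, Optional

from .constants import (
    occasions_per_month_to_per_day,
    occasions_per_week_to_per_day,
)
from .errors import ValidationError

__all__ = [
    "FrequencyCategory",
    "AuditCResult",
    "RiskStatus",
    "DEFAULT_FREQUENCY_MIDPOINTS",
    "DEFAULT_QUANTITY_MIDPOINTS",
    "FEMALE_RISK_THRESHOLD",
    "MALE_RISK_THRESHOLD",
    "derive_audit2m",
    "score_audit1m",
    "score_audit3mv",
    "total_audit_cm",
    "frequency_midpoint_per_day",
    "quantity_midpoint",
    "audit12_risk",
    "audit3_risk",
    "occasions_per_week_to_per_day",
]


class FrequencyCategory(IntEnum):
    """Ordinal frequency response; the item score is the ordinal position."""

    NEVER = 0
    LT_MONTHLY = 1  # "once in a blue moon" (less than monthly)
    MONTHLY_1_3 = 2  # "sometimes" (1-3 times a month)
    WEEKLY_1_3 = 3  # "a few times a week"
    MOST_DAYS = 4  # "most days or every day"

    @classmethod
    def from_token(cls, token: str) -> "FrequencyCategory":
        try:
            return _TOKEN_TO_CATEGORY[token]
        except KeyError:
            raise ValidationError(
                f"unknown frequency token {token!r}; expected one of "
                f"{sorted(_TOKEN_TO_CATEGORY)}"
            ) from None

    @property
    def token(self) -> str:
        return self.name.lower()


_TOKEN_TO_CATEGORY = {c.name.lower(): c for c in FrequencyCategory}

#: Midpoint of each frequency category, in occasions per day.  The scale
#: anchors at weekly drinking = 1/7 = 0.14/day; the less-than-monthly
#: category takes the midpoint of 0-1 occasions/month, the monthly category
#: 2/month, the weekly category 2/week, and the top (open) category 5.5/week.
DEFAULT_FREQUENCY_MIDPOINTS: Mapping[FrequencyCategory, float] = {
    FrequencyCategory.NEVER: 0.0,
    FrequencyCategory.LT_MONTHLY: occasions_per_month_to_per_day(0.5),
    FrequencyCategory.MONTHLY_1_3: occasions_per_month_to_per_day(2.0),
    FrequencyCategory.WEEKLY_1_3: occasions_per_week_to_per_day(2.0),
    FrequencyCategory.MOST_DAYS: occasions_per_week_to_per_day(5.5),
}

#: Midpoint of each AUDIT-2 quantity category in standard drinks; the open
#: top category (10+) is represented by 10.
DEFAULT_QUANTITY_MIDPOINTS: Mapping[int, float] = {0: 1.5, 1: 3.5, 2: 5.5, 3: 8.0, 4: 10.0}

FEMALE_RISK_THRESHOLD = 3
MALE_RISK_THRESHOLD = 4

#: Short-term risk rules (>4 drinks threshold on any single day): "guideline 2".
SHORT_TERM_DRINKS_THRESHOLD = 4.0
#: Long-term risk: average of more than two standard drinks per day.
LONG_TERM_DRINKS_PER_DAY_THRESHOLD = 2.0
#: Quantity the visual 5+-drinks item asks about, used for its long-term rule.
AUDIT3_VISUAL_DRINKS = 5.0


@dataclass(frozen=True)
class AuditCResult:
    """Scored AUDIT-Cm: three item scores, the total and the sex-rule flag."""

    audit1m_score: int
    audit2m_score: int
    audit3mv_score: int
    total: int
    at_risk: bool


@dataclass(frozen=True)
class RiskStatus:
    """Short-/long-term risk flags produced by a named screening method."""

    method: str
    short_term: bool
    long_term: bool

    @property
    def any_risk(self) -> bool:
        return self.short_term or self.long_term


def _check_score(name: str, score: int) -> None:
    if score not in (0, 1, 2, 3, 4):
        raise ValidationError(f"{name} must be an integer 0-4, got {score!r}")


def derive_audit2m(usual_drinks_per_occasion: float) -> int:
    """Recode the continuous usual quantity into the AUDIT-2 item score.

    The value is rounded half-up to a whole number of drinks (the printed
    categories are integer drink counts), then mapped: 0-2 drinks -> 0,
    3-4 -> 1, 5-6 -> 2, 7-9 -> 3, 10 or more -> 4.
    """
    if usual_drinks_per_occasion < 0:
        raise ValidationError(
            f"usual_drinks_per_occasion must be >= 0, got {usual_drinks_per_occasion!r}"
        )
    drinks = math.floor(usual_drinks_per_occasion + 0.5)
    if drinks <= 2:
        return 0
    if drinks <= 4:
        return 1
    if drinks <= 6:
        return 2
    if drinks <= 9:
        return 3
    return 4


def score_audit1m(
    category: FrequencyCategory, past_year_drinker: bool = True
) -> int:
    """Score the AUDIT-1m frequency item (ordinal position 0-4).

    AUDIT-1m is only asked of confirmed past-year drinkers, so for them a
    NEVER response is invalid.
    """
    category = FrequencyCategory(category)
    if past_year_drinker and category is FrequencyCategory.NEVER:
        raise ValidationError(
            "AUDIT-1m has no 'never' option for past-year drinkers"
        )
    return int(category)


def score_audit3mv(category: FrequencyCategory) -> int:
    """Score the AUDIT-3mV (5+ drinks frequency) item: ordinal position 0-4."""
    return int(FrequencyCategory(category))


def total_audit_cm(
    audit1m_score: int,
    audit2m_score: int,
    audit3mv_score: int,
    sex: str,
    female_threshold: int = FEMALE_RISK_THRESHOLD,
    male_threshold: int = MALE_RISK_THRESHOLD,
) -> AuditCResult:
    """Total the three AUDIT-Cm items and apply the sex-specific risk rule:
    at risk when the total is >= 3 for women, >= 4 for men."""
    for name, score in (
        ("audit1m_score", audit1m_score),
        ("audit2m_score", audit2m_score),
        ("audit3mv_score", audit3mv_score),
    ):
        _check_score(name, score)
    if sex not in ("female", "male"):
        raise ValidationError(f"sex must be 'female' or 'male', got {sex!r}")
    total = audit1m_score + audit2m_score + audit3mv_score
    threshold = female_threshold if sex == "female" else male_threshold
    return AuditCResult(
        audit1m_score=audit1m_score,
        audit2m_score=audit2m_score,
        audit3mv_score=audit3mv_score,
        total=total,
        at_risk=total >= threshold,
    )


def frequency_midpoint_per_day(
    category: FrequencyCategory,
    midpoints: Optional[Mapping[FrequencyCategory, float]] = None,
) -> float:
    """Occasions per day at the midpoint of a frequency response category."""
    category = FrequencyCategory(category)
    table = DEFAULT_FREQUENCY_MIDPOINTS if midpoints is None else midpoints
    try:
        return table[category]
    except KeyError:
        raise ValidationError(f"no midpoint configured for {category!r}") from None


def quantity_midpoint(
    audit2m_score: int,
    midpoints: Optional[Mapping[int, float]] = None,
) -> float:
    """Standard drinks at the midpoint of an AUDIT-2m score category."""
    _check_score("audit2m_score", audit2m_score)
    table = DEFAULT_QUANTITY_MIDPOINTS if midpoints is None else midpoints
    return table[audit2m_score]


def audit12_risk(
    audit1m_category: FrequencyCategory,
    audit2m_score: int,
    short_term_min_frequency: str = "any_past_year",
    frequency_midpoints: Optional[Mapping[FrequencyCategory, float]] = None,
    quantity_midpoints: Optional[Mapping[int, float]] = None,
) -> RiskStatus:
    """Risk estimated from AUDIT-1m + AUDIT-2m alone.

    Short-term risk: the quantity midpoint exceeds four standard drinks and
    the person drinks at all (frequency category above NEVER).  With
    ``short_term_min_frequency='monthly'`` drinking at least monthly is
    required instead of at least once in the year.

    Long-term risk: frequency midpoint (occasions/day) x quantity midpoint
    (drinks/occasion) exceeds two drinks per day.
    """
    category = FrequencyCategory(audit1m_category)
    if short_term_min_frequency not in ("any_past_year", "monthly"):
        raise ValidationError(
            "short_term_min_frequency must be 'any_past_year' or 'monthly', "
            f"got {short_term_min_frequency!r}"
        )
    qmid = quantity_midpoint(audit2m_score, quantity_midpoints)
    fmid = frequency_midpoint_per_day(category, frequency_midpoints)
    min_category = (
        FrequencyCategory.LT_MONTHLY
        if short_term_min_frequency == "any_past_year"
        else FrequencyCategory.MONTHLY_1_3
    )
    short = qmid > SHORT_TERM_DRINKS_THRESHOLD and category >= min_category
    long = fmid * qmid > LONG_TERM_DRINKS_PER_DAY_THRESHOLD
    return RiskStatus(method="audit_12", short_term=short, long_term=long)


def audit3_risk(
    audit3mv_category: FrequencyCategory,
    frequency_midpoints: Optional[Mapping[FrequencyCategory, float]] = None,
) -> RiskStatus:
    """Risk estimated from the AUDIT-3mV item alone.

    Short-term risk: any non-NEVER response (the item asks directly about
    >4-drink occasions).  Long-term risk: five standard drinks (the visual
    threshold the item shows) times the frequency midpoint exceeds two
    drinks per day — under the default midpoints this is equivalent to a
    MOST_DAYS response.
    """
    category = FrequencyCategory(audit3mv_category)
    fmid = frequency_midpoint_per_day(category, frequency_midpoints)
    return RiskStatus(
        method="audit_3",
        short_term=category is not FrequencyCategory.NEVER,
        long_term=AUDIT3_VISUAL_DRINKS * fmid > LONG_TERM_DRINKS_PER_DAY_THRESHOLD,
    )
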