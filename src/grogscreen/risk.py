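"""Drinker-status gating, dependence screening, and NHMRC guideline risk.

Past-year drinker status comes from two gate questions: a 'preparatory'
question (any alcohol in the last 12 months?) and, if that is answered no, a
'check' question about special events — added because respondents sometimes
assume only regular or heavy drinking counts.  Non-drinkers are excluded
from every downstream analysis.

The three-item dependence screen (ICD-11 based) only labels a sampling
stratum: any non-"never" rating marks the person as a likely-dependent
drinker.  It never enters risk computation.

NHMRC (2009 Australian guideline) risk from Finnish-method consumption:
long-term risk when average consumption exceeds two standard drinks per day,
short-term risk when more than four standard drinks were consumed on any
single recorded drinking day.  Both thresholds are strict inequalities.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional, Sequence

from .audit import FrequencyCategory, RiskStatus
from .errors import ValidationError
from .finnish import ConsumptionSummary

LONG_TERM_AVG_DRINKS_PER_DAY = 2.0
SHORT_TERM_SINGLE_OCCASION_DRINKS = 4.0


class DrinkerStatus(Enum):
    NON_DRINKER = "non_drinker"
    DRINKER = "drinker"


class DependenceStatus(Enum):
    NON_DEPENDENT = "non_dependent"
    DEPENDENT = "dependent"


def drinker_status(prep_drank: bool, check_drank: Optional[bool]) -> DrinkerStatus:
    """Classify past-year drinker status from the two gate questions.

    The check question must be answered whenever the preparatory answer is
    no; a yes to either question makes the person a drinker.
    """
    if prep_drank:
        return DrinkerStatus.DRINKER
    if check_drank is None:
        raise ValidationError(
            "check question must be answered when the preparatory answer is no"
        )
    return DrinkerStatus.DRINKER if check_drank else DrinkerStatus.NON_DRINKER


def dependence_status(ratings: Sequence[FrequencyCategory]) -> DependenceStatus:
    """DEPENDENT iff any of the three dependence items occurred at any
    frequency in the past year (any rating above never)."""
    if len(ratings) != 3:
        raise ValidationError(f"expected 3 dependence ratings, got {len(ratings)}")
    cats = [FrequencyCategory(r) for r in ratings]
    if any(c > FrequencyCategory.NEVER for c in cats):
        return DependenceStatus.DEPENDENT
    return DependenceStatus.NON_DEPENDENT


def nhmrc_risk(
    average_drinks_per_day: float, max_single_occasion: float
) -> RiskStatus:
    """Apply the NHMRC guideline rules to Finnish-method estimates.

    Strict thresholds: exactly 2.0 drinks/day average or exactly 4.0 drinks
    on the heaviest day is NOT at risk.
    """
    if average_drinks_per_day < 0 or max_single_occasion < 0:
        raise ValidationError("consumption estimates must be >= 0")
    return RiskStatus(
        method="finnish",
        short_term=max_single_occasion > SHORT_TERM_SINGLE_OCCASION_DRINKS,
        long_term=average_drinks_per_day > LONG_TERM_AVG_DRINKS_PER_DAY,
    )


def nhmrc_risk_from_summary(summary: ConsumptionSummary) -> RiskStatus:
    """Convenience wrapper taking a full Finnish-method summary."""
    return nhmrc_risk(summary.average_drinks_per_day, summary.max_single_occasion)
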