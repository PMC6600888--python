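"""Finnish-method consumption estimation from the last k <= 4 drinking occasions.

The Finnish method asks about the timing and quantity of a person's most
recent drinking occasions (here up to four, within the past year) and derives:

* drinking frequency (occasions per month) from the timing of the k most
  recent occasions,
* drinks per occasion (intensity) as the mean quantity over the k most
  recent occasions,
* average drinks per day as intensity x frequency / days-per-month,
* the maximum single-occasion quantity, which drives short-term risk.

Frequency uses a renewal-style estimator: k occasions divided by the days
back to the k-th most recent occasion, scaled to a month.  The span is
clamped to at least one day so a same-day occasion does not divide by zero.
Shortened variants (k < 4) use the same formulas so the full and shortened
estimates are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .constants import DAYS_PER_MONTH, PAST_YEAR_WINDOW_DAYS
from .consumption import Catalog, DrinkingOccasion, occasion_quantities
from .errors import UndefinedStatisticError, ValidationError


@dataclass(frozen=True)
class ConsumptionSummary:
    """Finnish-method estimates for one drinker.

    ``k_quantity`` occasions were used for intensity, ``k_frequency`` for
    frequency.  The identity ``average_drinks_per_day ==
    drinks_per_occasion * frequency_per_month / DAYS_PER_MONTH`` holds by
    construction.
    """

    k_quantity: int
    k_frequency: int
    frequency_per_month: float
    drinks_per_occasion: float
    average_drinks_per_day: float
    max_single_occasion: float


def _require_sorted(occasions: Sequence[DrinkingOccasion]) -> None:
    days = [o.days_before_survey for o in occasions]
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValidationError(
            "occasions must be sorted most-recent-first "
            f"(non-decreasing days_before_survey), got {days}"
        )


def _check_k(name: str, k: int, available: int) -> None:
    if not 1 <= k <= available:
        raise ValidationError(
            f"{name} must lie in [1, {available}] (occasions available), got {k}"
        )


def past_year_occasions(
    occasions: Sequence[DrinkingOccasion],
    window_days: int = PAST_YEAR_WINDOW_DAYS,
) -> list:
    """Occasions within the recall window, most recent first.

    Occasions older than ``window_days`` are excluded before any estimate is
    computed; a person left with zero occasions is a past-year non-drinker
    for analysis purposes.
    """
    _require_sorted(occasions)
    return [o for o in occasions if o.days_before_survey <= window_days]


def drinking_frequency(
    occasions: Sequence[DrinkingOccasion],
    k_frequency: int,
    days_per_month: float = DAYS_PER_MONTH,
) -> float:
    """Drinking frequency in occasions per month from occasion timing.

    frequency = k / span * days_per_month, where span is the
    days-before-survey of the k-th most recent occasion, clamped to >= 1.
    """
    if not occasions:
        raise UndefinedStatisticError(
            "frequency is undefined with no occasions; treat as non-drinker"
        )
    _require_sorted(occasions)
    _check_k("k_frequency", k_frequency, len(occasions))
    span = max(occasions[k_frequency - 1].days_before_survey, 1)
    return k_frequency / span * days_per_month


def drinks_per_occasion(
    occasions: Sequence[DrinkingOccasion],
    k_quantity: int,
    catalog: Optional[Catalog] = None,
) -> float:
    """Mean standard drinks over the k most recent occasions."""
    if not occasions:
        raise UndefinedStatisticError("drinks per occasion undefined with no occasions")
    _require_sorted(occasions)
    _check_k("k_quantity", k_quantity, len(occasions))
    quantities = occasion_quantities(occasions[:k_quantity], catalog)
    return sum(quantities) / k_quantity


def average_drinks_per_day(
    occasions: Sequence[DrinkingOccasion],
    k_quantity: int,
    k_frequency: int,
    catalog: Optional[Catalog] = None,
    days_per_month: float = DAYS_PER_MONTH,
) -> float:
    """Average standard drinks per day: intensity x frequency / days-per-month.

    For ``k_quantity == k_frequency == k`` this reduces algebraically to
    (sum of the k quantities) / span.
    """
    intensity = drinks_per_occasion(occasions, k_quantity, catalog)
    frequency = drinking_frequency(occasions, k_frequency, days_per_month)
    return intensity * frequency / days_per_month


def max_drinks_single_occasion(
    occasions: Sequence[DrinkingOccasion],
    catalog: Optional[Catalog] = None,
) -> float:
    """Maximum standard drinks on any recorded occasion."""
    if not occasions:
        raise UndefinedStatisticError("maximum undefined with no occasions")
    return max(occasion_quantities(occasions, catalog))


def summarize(
    occasions: Sequence[DrinkingOccasion],
    k_quantity: int = 4,
    k_frequency: int = 4,
    catalog: Optional[Catalog] = None,
    window_days: int = PAST_YEAR_WINDOW_DAYS,
    days_per_month: float = DAYS_PER_MONTH,
) -> ConsumptionSummary:
    """Full Finnish-method summary for one drinker.

    The instrument records at most the four most recent in-window occasions,
    so every estimate — including the single-occasion maximum — is computed
    over those records only.  ``k_quantity`` / ``k_frequency`` are clamped
    down to the number of recorded occasions so people with fewer than four
    past-year occasions still get an estimate from what they reported.
    """
    windowed = past_year_occasions(occasions, window_days)
    if not windowed:
        raise UndefinedStatisticError(
            "no occasions within the recall window; treat as past-year non-drinker"
        )
    recorded = windowed[:4]
    kq = min(k_quantity, len(recorded))
    kf = min(k_frequency, len(recorded))
    intensity = drinks_per_occasion(recorded, kq, catalog)
    frequency = drinking_frequency(recorded, kf, days_per_month)
    return ConsumptionSummary(
        k_quantity=kq,
        k_frequency=kf,
        frequency_per_month=frequency,
        drinks_per_occasion=intensity,
        average_drinks_per_day=intensity * frequency / days_per_month,
        max_single_occasion=max_drinks_single_occasion(recorded, catalog),
    )
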