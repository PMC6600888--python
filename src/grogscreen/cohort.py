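"""Synthetic survey cohorts with intermittent heavy-drinking structure.

The study population this emulates drinks intermittently (most commonly 1-3
times a month) but heavily per occasion (median 16-18 standard drinks), and
was recruited by stratified sampling of non-drinkers, non-dependent drinkers
and likely-dependent drinkers.  Real participant-level data cannot be
released, so this module generates cohorts with the same statistical
structure so every pipeline stage is testable end to end.

Model
-----
* Strata: a participant is a non-drinker with probability
  ``prop_non_drinker``; drinkers are labelled dependent with probability
  ``prop_dependent`` (a sampling label only — it never affects consumption).
* Timing: each drinker has a latent drinking rate (occasions/day) drawn
  log-uniformly within the band of a frequency class sampled from
  ``frequency_class_probs`` (the four drinker classes of the AUDIT-1m item).
  Occasion offsets follow a renewal process: i.i.d. exponential gaps
  accumulated backwards from a uniform first offset, truncated at the recall
  window.
* Quantity: per-occasion standard drinks follow a two-component log-normal
  mixture.  Most drinkers centre on ``quantity_median``; a small
  light-drinking subgroup (``prop_light_drinker``) centres on
  ``light_quantity_median``.  Around the component median there is a
  between-person spread (sigma_between) and a within-person spread across
  occasions (sigma_within).  The structure matters: short-term risk is
  escaped only by people whose *every* recorded occasion stays at or below
  four drinks, which requires a distinct light-drinking minority alongside
  the heavy majority.
* Self-report: true AUDIT-1m / AUDIT-3mV categories are read off the latent
  rates, then optionally perturbed to an adjacent category with probability
  ``report_noise``.

One seed drives everything; regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .audit import FrequencyCategory
from .constants import DAYS_PER_MONTH, PAST_YEAR_WINDOW_DAYS
from .consumption import (
    BeverageEntry,
    BeverageProduct,
    Catalog,
    DrinkingOccasion,
    entry_standard_drinks,
)
from .errors import ValidationError

#: Frequency-class rate bands in occasions/day (log-uniform within band).
#: Boundaries at 1/month, 1/week and 3.5/week match the category binning.
_RATE_BANDS: Tuple[Tuple[float, float], ...] = (
    (4.0 / PAST_YEAR_WINDOW_DAYS, 1.0 / DAYS_PER_MONTH),  # less than monthly
    (1.0 / DAYS_PER_MONTH, 1.0 / 7.0),  # 1-3 times a month
    (1.0 / 7.0, 3.5 / 7.0),  # a few times a week
    (3.5 / 7.0, 1.0),  # most days
)

_DRINKER_CLASSES = (
    FrequencyCategory.LT_MONTHLY,
    FrequencyCategory.MONTHLY_1_3,
    FrequencyCategory.WEEKLY_1_3,
    FrequencyCategory.MOST_DAYS,
)


@dataclass(frozen=True)
class CohortParams:
    """Generator settings; the defaults are calibrated to the survey
    population the analysis is designed for: stratified recruitment of 20%
    non-drinkers, half of drinkers likely dependent, the published
    frequency-class marginals, a median of 16-18 standard drinks per
    occasion, and a small light-drinking minority that keeps a realistic
    ~5% of drinkers below the short-term risk threshold."""

    n_participants: int = 230
    prop_non_drinker: float = 0.2
    prop_dependent: float = 0.5
    #: P(frequency class) over LT_MONTHLY, MONTHLY_1_3, WEEKLY_1_3, MOST_DAYS.
    frequency_class_probs: Tuple[float, float, float, float] = (0.304, 0.424, 0.261, 0.011)
    quantity_median: float = 18.0
    light_quantity_median: float = 2.5
    prop_light_drinker: float = 0.07
    sigma_between: float = 0.65
    sigma_within: float = 0.25
    report_noise: float = 0.0
    copy_last_quantity_prob: float = 0.0
    window_days: int = PAST_YEAR_WINDOW_DAYS
    bursty: bool = False
    burst_rate_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        for name in ("prop_non_drinker", "prop_dependent", "report_noise",
                     "copy_last_quantity_prob", "prop_light_drinker"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")
        if len(self.frequency_class_probs) != 4:
            raise ValidationError("frequency_class_probs must have 4 entries")
        if any(p < 0 for p in self.frequency_class_probs):
            raise ValidationError("frequency_class_probs must be non-negative")
        if not math.isclose(sum(self.frequency_class_probs), 1.0, abs_tol=1e-6):
            raise ValidationError("frequency_class_probs must sum to 1")
        if self.quantity_median <= 0 or self.light_quantity_median <= 0:
            raise ValidationError("quantity medians must be > 0")
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValidationError("sigmas must be >= 0")
        if self.window_days < 1:
            raise ValidationError("window_days must be >= 1")
        if self.burst_rate_multiplier < 1:
            raise ValidationError("burst_rate_multiplier must be >= 1")


@dataclass(frozen=True)
class ParticipantRecord:
    """One synthetic participant, occasions most recent first."""

    person_id: str
    sex: str
    prep_drank: bool
    check_drank: Optional[bool]
    dependence_ratings: Tuple[FrequencyCategory, FrequencyCategory, FrequencyCategory]
    latent_rate: Optional[float]  # occasions/day; None for non-drinkers
    occasions: Tuple[DrinkingOccasion, ...]
    audit1m: Optional[FrequencyCategory]
    audit3mv: Optional[FrequencyCategory]

    @property
    def is_drinker(self) -> bool:
        return self.prep_drank or bool(self.check_drank)

    @property
    def has_four_occasions(self) -> bool:
        return len(self.occasions) >= 4


def default_catalog() -> Catalog:
    """A small product catalog for beverage-dialect output and round trips."""
    products = [
        BeverageProduct("beer_can_full", "full-strength beer, 375 mL can", 0.048),
        BeverageProduct("wine_bottle", "table wine, 750 mL bottle", 0.135),
        BeverageProduct("spirits_bottle", "spirits, 700 mL bottle", 0.40),
    ]
    return {p.product_id: p for p in products}

#: Container volume (mL) used when composing entries for each catalog product.
_CONTAINER_ML = {"beer_can_full": 375.0, "wine_bottle": 750.0, "spirits_bottle": 700.0}


def compose_beverages(
    target_drinks: float,
    catalog: Catalog,
    product_id: Optional[str] = None,
) -> List[BeverageEntry]:
    """Compose beverage entries whose converted total equals ``target_drinks``.

    Greedy fill: as many whole containers of one product as fit, plus one
    partially full container for the remainder.  The round trip through
    the occasion conversion is exact to ~1e-9 relative.
    """
    if target_drinks < 0:
        raise ValidationError(f"target_drinks must be >= 0, got {target_drinks!r}")
    if not catalog:
        raise ValidationError("catalog must not be empty")
    if target_drinks == 0:
        return []
    if product_id is None:
        product_id = sorted(catalog)[0]
    if product_id not in catalog:
        raise ValidationError(f"product_id {product_id!r} not in catalog")
    product = catalog[product_id]
    volume = _CONTAINER_ML.get(product_id, 375.0)
    per_full = entry_standard_drinks(
        BeverageEntry(product_id, volume), catalog
    )
    n_full = int(target_drinks // per_full)
    remainder = target_drinks - n_full * per_full
    entries: List[BeverageEntry] = []
    if n_full:
        entries.append(BeverageEntry(product_id, volume, count=float(n_full)))
    if remainder > 1e-12 * max(target_drinks, 1.0):
        entries.append(BeverageEntry(product_id, volume, fullness=remainder / per_full))
    return entries


def _rate_to_category(rate_per_day: float) -> FrequencyCategory:
    if rate_per_day < 1.0 / DAYS_PER_MONTH:
        return FrequencyCategory.LT_MONTHLY
    if rate_per_day < 1.0 / 7.0:
        return FrequencyCategory.MONTHLY_1_3
    if rate_per_day < 3.5 / 7.0:
        return FrequencyCategory.WEEKLY_1_3
    return FrequencyCategory.MOST_DAYS


def generate_occasions(
    rng: np.random.Generator,
    latent_rate: float,
    person_median: float,
    sigma_within: float,
    window_days: int = PAST_YEAR_WINDOW_DAYS,
    copy_last_quantity_prob: float = 0.0,
    bursty: bool = False,
    burst_rate_multiplier: float = 3.0,
) -> Tuple[DrinkingOccasion, ...]:
    """Simulate in-window drinking occasions for one drinker.

    Offsets: exponential inter-occasion gaps (mean 1/latent_rate) accumulated
    backwards in time from a first offset uniform on [0, 1/latent_rate];
    anything beyond the recall window is dropped.  Quantities: log-normal
    around the person's median.  With ``bursty``, the process alternates
    between an "on" state (rate multiplied) and an "off" state (rate
    divided), emulating stop-start drinking runs.
    """
    if latent_rate <= 0:
        raise ValidationError(f"latent_rate must be > 0, got {latent_rate!r}")
    mean_gap = 1.0 / latent_rate
    t = min(rng.uniform(0.0, mean_gap), float(window_days) - 1.0)
    offsets = []
    state_on = True
    while t <= window_days:
        offsets.append(t)
        gap_mean = mean_gap
        if bursty:
            gap_mean = mean_gap / burst_rate_multiplier if state_on else mean_gap * burst_rate_multiplier
            if rng.random() < 0.2:  # occasional switch between runs and gaps
                state_on = not state_on
        t += rng.exponential(gap_mean)
    quantities = person_median * np.exp(sigma_within * rng.standard_normal(len(offsets)))
    if copy_last_quantity_prob > 0 and len(offsets) > 1:
        copy = rng.random(len(offsets) - 1) < copy_last_quantity_prob
        quantities[1:][copy] = quantities[0]
    return tuple(
        DrinkingOccasion(
            days_before_survey=int(round(day)),
            standard_drinks=float(q),
        )
        for day, q in zip(offsets, quantities)
    )


def report_categories(
    rng: np.random.Generator,
    latent_rate: float,
    occasions: Sequence[DrinkingOccasion],
    noise: float = 0.0,
) -> Tuple[FrequencyCategory, FrequencyCategory]:
    """Self-reported AUDIT-1m and AUDIT-3mV categories for a drinker.

    The true AUDIT-1m category bins the latent overall rate; the true
    AUDIT-3mV category bins the latent rate of >4-drink occasions (overall
    rate times the observed fraction of heavy occasions), NEVER when no
    recorded occasion exceeded four drinks.  With probability ``noise`` a
    reported category moves one level up or down (clamped to the valid
    range; AUDIT-1m never falls to NEVER, which drinkers cannot answer).
    """
    audit1m = _rate_to_category(latent_rate)
    heavy = [o for o in occasions if float(o.standard_drinks) > 4.0]
    if not heavy:
        audit3mv = FrequencyCategory.NEVER
    else:
        heavy_rate = latent_rate * len(heavy) / len(occasions)
        audit3mv = _rate_to_category(heavy_rate)

    def perturb(cat: FrequencyCategory, floor: int) -> FrequencyCategory:
        if noise <= 0 or rng.random() >= noise:
            return cat
        step = 1 if rng.random() < 0.5 else -1
        return FrequencyCategory(int(np.clip(int(cat) + step, floor, 4)))

    return perturb(audit1m, floor=1), perturb(audit3mv, floor=0)


def _dependence_ratings(
    rng: np.random.Generator, dependent: bool
) -> Tuple[FrequencyCategory, FrequencyCategory, FrequencyCategory]:
    never = FrequencyCategory.NEVER
    if not dependent:
        return (never, never, never)
    ratings = [FrequencyCategory(int(c)) for c in rng.choice(5, size=3, p=[0.35, 0.3, 0.2, 0.1, 0.05])]
    if all(r is never for r in ratings):
        ratings[0] = FrequencyCategory(int(rng.integers(1, 5)))
    return tuple(ratings)


def generate_cohort(params: CohortParams, seed: int) -> List[ParticipantRecord]:
    """Generate a full synthetic cohort, deterministic given ``seed``."""
    if not isinstance(params, CohortParams):
        raise ValidationError("params must be a CohortParams instance")
    rng = np.random.default_rng(seed)
    records: List[ParticipantRecord] = []
    class_probs = np.asarray(params.frequency_class_probs, dtype=float)
    class_probs = class_probs / class_probs.sum()
    for i in range(params.n_participants):
        person_id = f"p{i:04d}"
        sex = "female" if rng.random() < 0.5 else "male"
        is_drinker = rng.random() >= params.prop_non_drinker
        if not is_drinker:
            records.append(
                ParticipantRecord(
                    person_id=person_id,
                    sex=sex,
                    prep_drank=False,
                    check_drank=False,
                    dependence_ratings=_dependence_ratings(rng, False),
                    latent_rate=None,
                    occasions=(),
                    audit1m=None,
                    audit3mv=None,
                )
            )
            continue
        dependent = rng.random() < params.prop_dependent
        # the check-question path: some drinkers first answer "no" to the
        # preparatory question, then "yes" for special events
        prep = rng.random() >= 0.1
        check = None if prep else True
        klass = int(rng.choice(4, p=class_probs))
        lo, hi = _RATE_BANDS[klass]
        rate = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        component_median = (
            params.light_quantity_median
            if rng.random() < params.prop_light_drinker
            else params.quantity_median
        )
        person_median = component_median * float(
            np.exp(params.sigma_between * rng.standard_normal())
        )
        occasions = generate_occasions(
            rng,
            rate,
            person_median,
            params.sigma_within,
            window_days=params.window_days,
            copy_last_quantity_prob=params.copy_last_quantity_prob,
            bursty=params.bursty,
            burst_rate_multiplier=params.burst_rate_multiplier,
        )
        audit1m, audit3mv = report_categories(rng, rate, occasions, params.report_noise)
        records.append(
            ParticipantRecord(
                person_id=person_id,
                sex=sex,
                prep_drank=prep,
                check_drank=check,
                dependence_ratings=_dependence_ratings(rng, dependent),
                latent_rate=rate,
                occasions=occasions,
                audit1m=audit1m,
                audit3mv=audit3mv,
            )
        )
    return records
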