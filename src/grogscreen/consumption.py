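"""Ethanol bookkeeping: beverage records -> grams of ethanol -> standard drinks.

Drinking surveys in communities where alcohol is shared and poured into
non-standard containers cannot ask for "standard drinks" directly.  Instead a
drinking occasion is recorded as a list of beverage entries (product, container
volume, how full it was, how many containers, and what share of the poured
amount the respondent actually drank).  This module converts such entries into
grams of pure ethanol and Australian standard drinks (10 g ethanol each).

Two input dialects exist for an occasion: a *beverage* dialect carrying
:class:`BeverageEntry` lists, and a *drinks* dialect carrying a pre-converted
standard-drinks total.  Both are represented by :class:`DrinkingOccasion`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .errors import CatalogLookupError, ValidationError

#: Density of pure ethanol, grams per millilitre.
ETHANOL_DENSITY_G_PER_ML: float = 0.789

#: One Australian standard drink contains 10 g of pure ethanol.
GRAMS_PER_STANDARD_DRINK: float = 10.0


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class BeverageProduct:
    """An alcohol product as listed in the catalog.

    ``abv`` is the ethanol fraction by volume, stored internally as a
    fraction in (0, 1); catalog files store it as a percent.
    """

    product_id: str
    name: str
    abv: float

    def __post_init__(self) -> None:
        if not 0.0 < self.abv < 1.0:
            raise ValidationError(
                f"abv must be a fraction in (0, 1), got {self.abv!r} "
                f"for product {self.product_id!r}"
            )


#: A product catalog maps product_id to the product description.
Catalog = Mapping[str, BeverageProduct]


@dataclass(frozen=True)
class BeverageEntry:
    """One beverage line within a drinking occasion.

    ``fullness`` is how full the container was, ``share`` the fraction of the
    poured amount this person drank, and ``count`` the number of such
    containers (fractional counts are allowed: half a shared can is
    equivalently count=0.5 or share=0.5).
    """

    product_id: str
    container_volume_ml: float
    fullness: float = 1.0
    count: float = 1.0
    share: float = 1.0

    def __post_init__(self) -> None:
        if self.container_volume_ml <= 0:
            raise ValidationError(
                f"container_volume_ml must be > 0, got {self.container_volume_ml!r}"
            )
        _check_fraction("fullness", self.fullness)
        _check_fraction("share", self.share)
        if self.count < 0:
            raise ValidationError(f"count must be >= 0, got {self.count!r}")


@dataclass(frozen=True)
class DrinkingOccasion:
    """One drinking day: an offset in days before the survey plus either a
    beverage-entry list or a pre-converted standard-drinks total.

    Exactly one of ``entries`` / ``standard_drinks`` must be populated.  An
    empty entry tuple is a valid beverage-dialect occasion totalling zero.
    """

    days_before_survey: int
    entries: Optional[tuple] = None
    standard_drinks: Optional[float] = None

    def __post_init__(self) -> None:
        if self.days_before_survey < 0:
            raise ValidationError(
                f"days_before_survey must be >= 0, got {self.days_before_survey!r}"
            )
        if (self.entries is None) == (self.standard_drinks is None):
            raise ValidationError(
                "exactly one of entries / standard_drinks must be populated"
            )
        if self.entries is not None:
            object.__setattr__(self, "entries", tuple(self.entries))
        if self.standard_drinks is not None and self.standard_drinks < 0:
            raise ValidationError(
                f"standard_drinks must be >= 0, got {self.standard_drinks!r}"
            )

    @property
    def is_beverage_dialect(self) -> bool:
        return self.entries is not None


def ethanol_grams(
    volume_ml: float,
    abv: float,
    fullness: float = 1.0,
    share: float = 1.0,
    count: float = 1.0,
) -> float:
    """Grams of pure ethanol in ``count`` containers of ``volume_ml`` at
    ``abv`` ethanol fraction, each ``fullness`` full, of which this person
    drank ``share``.

    grams = volume_ml x abv x fullness x share x count x 0.789 g/mL,
    linear in every factor.
    """
    if volume_ml <= 0:
        raise ValidationError(f"volume_ml must be > 0, got {volume_ml!r}")
    _check_fraction("abv", abv)
    _check_fraction("fullness", fullness)
    _check_fraction("share", share)
    if count < 0:
        raise ValidationError(f"count must be >= 0, got {count!r}")
    return volume_ml * abv * fullness * share * count * ETHANOL_DENSITY_G_PER_ML


def standard_drinks(grams: float) -> float:
    """Convert grams of ethanol to Australian standard drinks (10 g each)."""
    if grams < 0:
        raise ValidationError(f"grams must be >= 0, got {grams!r}")
    return grams / GRAMS_PER_STANDARD_DRINK


def entry_standard_drinks(entry: BeverageEntry, catalog: Catalog) -> float:
    """Standard drinks contributed by a single beverage entry."""
    product = catalog.get(entry.product_id)
    if product is None:
        raise CatalogLookupError(entry.product_id)
    grams = ethanol_grams(
        entry.container_volume_ml,
        product.abv,
        entry.fullness,
        entry.share,
        entry.count,
    )
    return standard_drinks(grams)


def occasion_total_drinks(
    occasion: DrinkingOccasion, catalog: Optional[Catalog] = None
) -> float:
    """Total standard drinks consumed on one occasion.

    Drinks-dialect occasions pass through unchanged; beverage-dialect
    occasions are summed over their entries, which requires every
    ``product_id`` to be present in ``catalog``.
    """
    if not occasion.is_beverage_dialect:
        return float(occasion.standard_drinks)
    if catalog is None:
        raise ValidationError(
            "a product catalog is required for beverage-dialect occasions"
        )
    missing = [e.product_id for e in occasion.entries if e.product_id not in catalog]
    if missing:
        raise CatalogLookupError(missing)
    return sum(entry_standard_drinks(e, catalog) for e in occasion.entries)


def occasion_quantities(
    occasions: Sequence[DrinkingOccasion], catalog: Optional[Catalog] = None
) -> list:
    """Standard-drinks totals for a sequence of occasions, in order."""
    return [occasion_total_drinks(o, catalog) for o in occasions]
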