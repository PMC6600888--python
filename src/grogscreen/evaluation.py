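"""Screening concordance and shortened-instrument evaluation.

Concordance between an index screening method and the Finnish-method
reference is summarised by a 2x2 cross-tabulation, sensitivity and
specificity, and exact (Clopper-Pearson) 95% confidence intervals — the
interval family that reproduces epidemiology-package output for small
denominators.

Accuracy retained by shortened Finnish variants is summarised by a 4x4 grid
of squared Pearson correlations: for each combination of k_quantity (rows)
and k_frequency (columns) in 1..4, the per-person estimate using that many
occasions is correlated against the full four-occasion estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import beta

from .consumption import Catalog, DrinkingOccasion, occasion_quantities
from .constants import PAST_YEAR_WINDOW_DAYS
from .errors import (
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)
from .finnish import average_drinks_per_day, drinks_per_occasion, past_year_occasions

RETENTION_VARIABLES = ("average_drinks_per_day", "drinks_per_occasion")


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 cross-tabulation of index-test vs reference risk flags."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def reference_positive(self) -> int:
        return self.tp + self.fn

    @property
    def index_positive(self) -> int:
        return self.tp + self.fp

    @property
    def disagreements(self) -> int:
        return self.fn + self.fp


@dataclass(frozen=True)
class ConcordanceResult:
    """Sensitivity/specificity point estimates with exact CIs."""

    table: TwoByTwo
    sensitivity: float
    specificity: float
    ci_sensitivity: Tuple[float, float]
    ci_specificity: Tuple[float, float]
    level: float = 0.95


@dataclass(frozen=True)
class RetentionGrid:
    """4x4 grid of r^2 values, rows = k_quantity, cols = k_frequency (1..4)."""

    r_squared: np.ndarray  # shape (4, 4)
    n_used: int
    n_excluded: int
    variable: str

    def entry(self, k_quantity: int, k_frequency: int) -> float:
        return float(self.r_squared[k_quantity - 1, k_frequency - 1])

    def as_percent(self) -> np.ndarray:
        return self.r_squared * 100.0


def cross_tabulate(
    index_flags: Sequence[bool], reference_flags: Sequence[bool]
) -> TwoByTwo:
    """Cross-tabulate index-test flags against reference flags.

    tp: both positive; fn: reference positive, index negative; fp: index
    positive, reference negative; tn: both negative.
    """
    if len(index_flags) != len(reference_flags):
        raise ValidationError(
            f"flag sequences differ in length: {len(index_flags)} vs {len(reference_flags)}"
        )
    tp = fn = fp = tn = 0
    for idx, ref in zip(index_flags, reference_flags):
        if ref and idx:
            tp += 1
        elif ref:
            fn += 1
        elif idx:
            fp += 1
        else:
            tn += 1
    return TwoByTwo(tp=tp, fn=fn, fp=fp, tn=tn)


def clopper_pearson(
    successes: int, n: int, level: float = 0.95
) -> Tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval via beta quantiles.

    The lower bound is 0 when there are no successes and the upper bound is
    1 when every trial succeeded; exact intervals are conservative (actual
    coverage at least the nominal level).
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n!r}")
    if not 0 <= successes <= n:
        raise ValidationError(f"successes must lie in [0, {n}], got {successes!r}")
    if not 0 < level < 1:
        raise ValidationError(f"level must lie in (0, 1), got {level!r}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


def sensitivity_specificity(table: TwoByTwo, level: float = 0.95) -> ConcordanceResult:
    """Sensitivity, specificity and their exact CIs from a 2x2 table."""
    if table.reference_positive < 1:
        raise UndefinedStatisticError(
            "sensitivity undefined: no reference-positive participants (tp + fn = 0)"
        )
    if table.fp + table.tn < 1:
        raise UndefinedStatisticError(
            "specificity undefined: no reference-negative participants (fp + tn = 0)"
        )
    sens = table.tp / table.reference_positive
    spec = table.tn / (table.fp + table.tn)
    return ConcordanceResult(
        table=table,
        sensitivity=sens,
        specificity=spec,
        ci_sensitivity=clopper_pearson(table.tp, table.reference_positive, level),
        ci_specificity=clopper_pearson(table.tn, table.fp + table.tn, level),
        level=level,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation, computed from mean-centred dot products."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be 1-d sequences of equal length")
    if xa.size < 3:
        raise ValidationError(f"need at least 3 observations, got {xa.size}")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedStatisticError("correlation undefined: zero variance")
    return float(xc @ yc) / float(np.sqrt(sxx) * np.sqrt(syy))


def _four_most_recent_quantities(
    occasions: Sequence[DrinkingOccasion],
    catalog: Optional[Catalog],
    window_days: int,
) -> Optional[list]:
    windowed = past_year_occasions(occasions, window_days)
    if len(windowed) < 4:
        return None
    return windowed[:4]


def retention_grid(
    occasions_by_person: Sequence[Sequence[DrinkingOccasion]],
    catalog: Optional[Catalog] = None,
    variable: str = "average_drinks_per_day",
    window_days: int = PAST_YEAR_WINDOW_DAYS,
) -> RetentionGrid:
    """r^2 retained by shortened Finnish variants against the full method.

    Only drinkers with at least four in-window occasions contribute; others
    are excluded and counted.  ``variable`` selects the correlated estimate:
    the default combines both axes (average drinks per day); the alternative
    correlates drinks-per-occasion, which depends on k_quantity only.
    The (4,4) entry is exactly 1.
    """
    if variable not in RETENTION_VARIABLES:
        raise ValidationError(
            f"variable must be one of {RETENTION_VARIABLES}, got {variable!r}"
        )
    eligible = []
    excluded = 0
    for occasions in occasions_by_person:
        four = _four_most_recent_quantities(occasions, catalog, window_days)
        if four is None:
            excluded += 1
        else:
            eligible.append(four)
    if len(eligible) < 3:
        raise InsufficientDataError(
            f"need >= 3 drinkers with 4 in-window occasions, got {len(eligible)}"
        )

    def estimate(occasions, kq, kf):
        if variable == "average_drinks_per_day":
            return average_drinks_per_day(occasions, kq, kf, catalog)
        return drinks_per_occasion(occasions, kq, catalog)

    full = np.array([estimate(o, 4, 4) for o in eligible])
    grid = np.empty((4, 4))
    for kq in range(1, 5):
        for kf in range(1, 5):
            if kq == 4 and kf == 4:
                grid[3, 3] = 1.0
                continue
            short = np.array([estimate(o, kq, kf) for o in eligible])
            grid[kq - 1, kf - 1] = pearson_r(short, full) ** 2
    return RetentionGrid(
        r_squared=grid,
        n_used=len(eligible),
        n_excluded=excluded,
        variable=variable,
    )


def exclude_zero_variance(
    occasions_by_person: Sequence[Sequence[DrinkingOccasion]],
    catalog: Optional[Catalog] = None,
    tol: float = 1e-9,
    window_days: int = PAST_YEAR_WINDOW_DAYS,
) -> Tuple[list, int]:
    """Drop drinkers whose four most recent quantities are all equal.

    Respondents could copy their most recent occasion as a default for
    earlier ones; excluding zero-variation cases checks that retention
    results do not rest on such stereotyped reporting.  Returns the filtered
    cohort and the number dropped.  Drinkers with fewer than four in-window
    occasions are kept (the retention grid excludes them separately).
    """
    kept = []
    dropped = 0
    for occasions in occasions_by_person:
        four = _four_most_recent_quantities(occasions, catalog, window_days)
        if four is not None:
            q = occasion_quantities(four, catalog)
            if max(q) - min(q) <= tol:
                dropped += 1
                continue
        kept.append(occasions)
    return kept, dropped
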