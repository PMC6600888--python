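"""Pipeline configuration: every analysis convention in one validated object.

The defaults reproduce the package's standard analysis; the switches exist
because the underlying conventions are genuinely open choices (midpoint
tables, the minimum frequency for subset short-term risk, which estimate the
retention grid correlates).  Configurations load from YAML with unknown keys
rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from .audit import (
    DEFAULT_FREQUENCY_MIDPOINTS,
    DEFAULT_QUANTITY_MIDPOINTS,
    FEMALE_RISK_THRESHOLD,
    MALE_RISK_THRESHOLD,
    FrequencyCategory,
)
from .cohort import CohortParams
from .constants import DAYS_PER_MONTH, PAST_YEAR_WINDOW_DAYS
from .errors import ValidationError
from .evaluation import RETENTION_VARIABLES


def _default_frequency_midpoints() -> Dict[str, float]:
    return {c.token: v for c, v in DEFAULT_FREQUENCY_MIDPOINTS.items()}


def _default_quantity_midpoints() -> Dict[int, float]:
    return dict(DEFAULT_QUANTITY_MIDPOINTS)


@dataclass
class PipelineConfig:
    days_per_month: float = DAYS_PER_MONTH
    window_days: int = PAST_YEAR_WINDOW_DAYS
    #: token -> occasions/day
    frequency_midpoints: Dict[str, float] = field(default_factory=_default_frequency_midpoints)
    #: AUDIT-2m score -> standard drinks
    quantity_midpoints: Dict[int, float] = field(default_factory=_default_quantity_midpoints)
    ci_method: str = "clopper_pearson"
    ci_level: float = 0.95
    short_term_min_frequency: str = "any_past_year"  # or "monthly"
    retention_variable: str = "average_drinks_per_day"
    female_threshold: int = FEMALE_RISK_THRESHOLD
    male_threshold: int = MALE_RISK_THRESHOLD
    cohort: CohortParams = field(default_factory=CohortParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days_per_month <= 0:
            raise ValidationError("days_per_month must be > 0")
        if self.window_days < 1:
            raise ValidationError("window_days must be >= 1")
        if self.ci_method != "clopper_pearson":
            raise ValidationError(
                f"unsupported ci_method {self.ci_method!r} (only clopper_pearson)"
            )
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must lie in (0, 1)")
        if self.short_term_min_frequency not in ("any_past_year", "monthly"):
            raise ValidationError(
                "short_term_min_frequency must be 'any_past_year' or 'monthly'"
            )
        if self.retention_variable not in RETENTION_VARIABLES:
            raise ValidationError(
                f"retention_variable must be one of {RETENTION_VARIABLES}"
            )
        expected_tokens = {c.token for c in FrequencyCategory}
        if set(self.frequency_midpoints) != expected_tokens:
            raise ValidationError(
                f"frequency_midpoints must have exactly the keys {sorted(expected_tokens)}"
            )
        if set(self.quantity_midpoints) != {0, 1, 2, 3, 4}:
            raise ValidationError("quantity_midpoints must have exactly the keys 0-4")
        if not 1 <= self.female_threshold <= self.male_threshold <= 12:
            raise ValidationError("require 1 <= female_threshold <= male_threshold <= 12")

    # -- derived views ----------------------------------------------------
    def frequency_midpoint_table(self) -> Dict[FrequencyCategory, float]:
        return {
            FrequencyCategory.from_token(tok): v
            for tok, v in self.frequency_midpoints.items()
        }

    # -- serialisation ----------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ValidationError("config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "cohort" in data and isinstance(data["cohort"], dict):
            cohort = dict(data["cohort"])
            cohort_known = {f.name for f in dataclasses.fields(CohortParams)}
            cohort_unknown = set(cohort) - cohort_known
            if cohort_unknown:
                raise ValidationError(f"unknown cohort keys: {sorted(cohort_unknown)}")
            if "frequency_class_probs" in cohort:
                cohort["frequency_class_probs"] = tuple(cohort["frequency_class_probs"])
            data["cohort"] = CohortParams(**cohort)
        if "quantity_midpoints" in data:
            data["quantity_midpoints"] = {int(k): float(v) for k, v in data["quantity_midpoints"].items()}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["cohort"]["frequency_class_probs"] = list(data["cohort"]["frequency_class_probs"])
        return data

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")
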