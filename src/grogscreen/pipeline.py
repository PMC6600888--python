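"""End-to-end analysis: survey files in, scored tables and concordance out.

Stages (drinkers only — non-drinkers are gated out first and counted):

1. Finnish-method consumption summary per drinker (k = min(4, in-window
   occasions)) and NHMRC short-/long-term risk from it (the reference).
2. AUDIT-Cm scoring: AUDIT-1m and AUDIT-3mV from the questionnaire,
   AUDIT-2m derived from the Finnish drinks-per-occasion estimate; total
   with sex-specific thresholds.
3. Risk from item subsets via category midpoints (AUDIT-1m+2m; AUDIT-3mV).
4. Concordance of each index method against the Finnish reference for
   any/short/long-term risk (2x2 tables, sensitivity/specificity, exact CIs).
5. Retention grid for shortened Finnish variants, plus a variant after
   excluding drinkers with zero variation across their four occasions.

Outputs: summary.csv, concordance.json, retention.csv,
retention_excluding_constant.csv, run_log.json.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import audit, finnish, risk
from .audit import FrequencyCategory
from .config import PipelineConfig
from .consumption import Catalog
from .errors import (
    GrogScreenError,
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)
from .evaluation import (
    RetentionGrid,
    cross_tabulate,
    exclude_zero_variance,
    retention_grid,
    sensitivity_specificity,
)
from .io import read_occasions, read_products, read_responses

logger = logging.getLogger("grogscreen")

INDEX_METHODS = ("audit_cm", "audit_12", "audit_3")
RISK_TYPES = ("any", "short", "long")

SUMMARY_COLUMNS = [
    "person_id", "k_quantity", "k_frequency", "freq_per_month",
    "drinks_per_occasion", "avg_drinks_per_day", "max_single_occasion",
    "audit1m_score", "audit2m_score", "audit3mv_score",
    "auditcm_total", "auditcm_at_risk",
    "drinker_status", "dependence_status",
    "finnish_short", "finnish_long", "finnish_any",
    "audit12_short", "audit12_long", "audit3_short", "audit3_long",
]


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    concordance: List[dict]
    retention: Optional[RetentionGrid]
    retention_excluding_constant: Optional[RetentionGrid]
    log: Dict[str, int]
    record_errors: List[str]


def _concordance_entry(method, risk_type, index_flags, reference_flags, level):
    table = cross_tabulate(index_flags, reference_flags)
    entry = {
        "method": method,
        "risk": risk_type,
        "reference": "finnish",
        "tp": table.tp, "fn": table.fn, "fp": table.fp, "tn": table.tn,
        "n": table.n,
    }
    try:
        result = sensitivity_specificity(table, level=level)
    except UndefinedStatisticError as exc:
        entry.update({"error": str(exc)})
        return entry
    entry.update({
        "sensitivity": result.sensitivity,
        "ci_sensitivity": list(result.ci_sensitivity),
        "specificity": result.specificity,
        "ci_specificity": list(result.ci_specificity),
        "sensitivity_pct": f"{result.sensitivity * 100:.1f}",
        "specificity_pct": f"{result.specificity * 100:.1f}",
        "ci_sensitivity_pct": [f"{b * 100:.1f}" for b in result.ci_sensitivity],
        "ci_specificity_pct": [f"{b * 100:.1f}" for b in result.ci_specificity],
    })
    return entry


def _retention_frame(grid: RetentionGrid) -> pd.DataFrame:
    rows = [
        {
            "k_quantity": kq,
            "k_frequency": kf,
            "r_squared_percent": round(grid.entry(kq, kf) * 100.0, 1),
        }
        for kq in range(1, 5)
        for kf in range(1, 5)
    ]
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    input_dir,
    output_dir=None,
) -> PipelineResult:
    """Run the full analysis over an input directory of survey CSVs.

    ``input_dir`` must contain responses.csv and occasions.csv; products.csv
    is required only for beverage-dialect occasions.  When ``output_dir`` is
    given the result tables are also written there.
    """
    input_dir = Path(input_dir)
    responses_path = input_dir / "responses.csv"
    occasions_path = input_dir / "occasions.csv"
    if not responses_path.exists():
        raise ValidationError(f"missing input file: {responses_path}")
    if not occasions_path.exists():
        raise ValidationError(f"missing input file: {occasions_path}")
    catalog: Optional[Catalog] = None
    products_path = input_dir / "products.csv"
    if products_path.exists():
        catalog = read_products(products_path)

    responses = read_responses(responses_path)
    occasions_by_person = read_occasions(occasions_path)

    record_errors: List[str] = []
    known_ids = {r.person_id for r in responses}
    for person_id in sorted(set(occasions_by_person) - known_ids):
        record_errors.append(
            f"occasions.csv references person_id {person_id!r} absent from responses.csv"
        )

    fmid = config.frequency_midpoint_table()
    qmid = config.quantity_midpoints

    n_non_drinkers = 0
    n_no_window = 0
    n_lt4 = 0
    rows = []
    flags = {(m, t): [] for m in INDEX_METHODS + ("finnish",) for t in RISK_TYPES}
    retention_input = []

    for resp in responses:
        status = risk.drinker_status(resp.prep_drank, resp.check_drank)
        if status is risk.DrinkerStatus.NON_DRINKER:
            n_non_drinkers += 1
            continue
        dep = risk.dependence_status(resp.dep_ratings)
        occasions = occasions_by_person.get(resp.person_id, [])
        try:
            windowed = finnish.past_year_occasions(occasions, config.window_days)
        except ValidationError as exc:
            record_errors.append(f"person {resp.person_id}: {exc}")
            continue
        if not windowed:
            n_no_window += 1
            logger.info("person %s: no in-window occasions; treated as past-year non-drinker",
                        resp.person_id)
            continue
        if len(windowed) < 4:
            n_lt4 += 1
        if resp.audit1m is None or resp.audit3mv is None:
            record_errors.append(
                f"person {resp.person_id}: drinker with missing AUDIT item responses"
            )
            continue

        summary = finnish.summarize(
            windowed, 4, 4,
            catalog=catalog,
            window_days=config.window_days,
            days_per_month=config.days_per_month,
        )
        finnish_risk = risk.nhmrc_risk_from_summary(summary)
        audit2m = audit.derive_audit2m(summary.drinks_per_occasion)
        scored = audit.total_audit_cm(
            audit.score_audit1m(resp.audit1m),
            audit2m,
            audit.score_audit3mv(resp.audit3mv),
            resp.sex,
            female_threshold=config.female_threshold,
            male_threshold=config.male_threshold,
        )
        r12 = audit.audit12_risk(
            resp.audit1m, audit2m,
            short_term_min_frequency=config.short_term_min_frequency,
            frequency_midpoints=fmid,
            quantity_midpoints=qmid,
        )
        r3 = audit.audit3_risk(resp.audit3mv, frequency_midpoints=fmid)

        retention_input.append(windowed)
        rows.append({
            "person_id": resp.person_id,
            "k_quantity": summary.k_quantity,
            "k_frequency": summary.k_frequency,
            "freq_per_month": summary.frequency_per_month,
            "drinks_per_occasion": summary.drinks_per_occasion,
            "avg_drinks_per_day": summary.average_drinks_per_day,
            "max_single_occasion": summary.max_single_occasion,
            "audit1m_score": scored.audit1m_score,
            "audit2m_score": scored.audit2m_score,
            "audit3mv_score": scored.audit3mv_score,
            "auditcm_total": scored.total,
            "auditcm_at_risk": scored.at_risk,
            "drinker_status": status.value,
            "dependence_status": dep.value,
            "finnish_short": finnish_risk.short_term,
            "finnish_long": finnish_risk.long_term,
            "finnish_any": finnish_risk.any_risk,
            "audit12_short": r12.short_term,
            "audit12_long": r12.long_term,
            "audit3_short": r3.short_term,
            "audit3_long": r3.long_term,
        })
        for risk_type, ref_flag in (
            ("any", finnish_risk.any_risk),
            ("short", finnish_risk.short_term),
            ("long", finnish_risk.long_term),
        ):
            flags[("finnish", risk_type)].append(ref_flag)
        # AUDIT-Cm is a single total-score flag, compared against each
        # reference risk type; the subsets produce their own short/long flags
        for risk_type in RISK_TYPES:
            flags[("audit_cm", risk_type)].append(scored.at_risk)
        flags[("audit_12", "any")].append(r12.any_risk)
        flags[("audit_12", "short")].append(r12.short_term)
        flags[("audit_12", "long")].append(r12.long_term)
        flags[("audit_3", "any")].append(r3.any_risk)
        flags[("audit_3", "short")].append(r3.short_term)
        flags[("audit_3", "long")].append(r3.long_term)

    summary_df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    n_drinkers = len(rows)

    concordance: List[dict] = []
    if n_drinkers:
        for method in INDEX_METHODS:
            for risk_type in RISK_TYPES:
                concordance.append(
                    _concordance_entry(
                        method, risk_type,
                        flags[(method, risk_type)],
                        flags[("finnish", risk_type)],
                        config.ci_level,
                    )
                )

    retention = retention_nzv = None
    n_zero_variance = 0
    try:
        retention = retention_grid(
            retention_input, catalog=catalog,
            variable=config.retention_variable,
            window_days=config.window_days,
        )
        filtered, n_zero_variance = exclude_zero_variance(
            retention_input, catalog=catalog, window_days=config.window_days
        )
        retention_nzv = retention_grid(
            filtered, catalog=catalog,
            variable=config.retention_variable,
            window_days=config.window_days,
        )
    except (InsufficientDataError, UndefinedStatisticError) as exc:
        logger.info("retention grid skipped: %s", exc)

    log = {
        "n_total": len(responses),
        "n_non_drinkers": n_non_drinkers,
        "n_no_window_occasions": n_no_window,
        "n_drinkers_analysed": n_drinkers,
        "n_fewer_than_4_occasions": n_lt4,
        "n_retention_eligible": retention.n_used if retention else 0,
        "n_zero_variance_dropped": n_zero_variance,
        "n_record_errors": len(record_errors),
    }
    for key, value in log.items():
        logger.info("%s = %d", key, value)

    result = PipelineResult(
        summary=summary_df,
        concordance=concordance,
        retention=retention,
        retention_excluding_constant=retention_nzv,
        log=log,
        record_errors=record_errors,
    )
    if output_dir is not None:
        write_outputs(result, output_dir)
    return result


def write_outputs(result: PipelineResult, output_dir) -> Dict[str, Path]:
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["summary"] = output_dir / "summary.csv"
    result.summary.to_csv(paths["summary"], index=False)

    paths["concordance"] = output_dir / "concordance.json"
    paths["concordance"].write_text(
        json.dumps(result.concordance, indent=2) + "\n", encoding="utf-8"
    )

    if result.retention is not None:
        paths["retention"] = output_dir / "retention.csv"
        _retention_frame(result.retention).to_csv(paths["retention"], index=False)
    if result.retention_excluding_constant is not None:
        paths["retention_excluding_constant"] = output_dir / "retention_excluding_constant.csv"
        _retention_frame(result.retention_excluding_constant).to_csv(
            paths["retention_excluding_constant"], index=False
        )

    paths["run_log"] = output_dir / "run_log.json"
    paths["run_log"].write_text(
        json.dumps({"counts": result.log, "record_errors": result.record_errors}, indent=2) + "\n",
        encoding="utf-8",
    )
    return paths
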