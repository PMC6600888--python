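"""CSV readers/writers for the survey file formats.

All files are UTF-8 comma-separated with required headers and '.' decimal
separators.  Formats:

* ``products.csv`` — ``product_id,name,abv_percent`` (abv stored as percent
  in files, converted to a fraction at this boundary only).
* ``occasions.csv``, drinks dialect —
  ``person_id,occasion_rank,days_before_survey,standard_drinks``.
* ``occasions.csv``, beverage dialect —
  ``person_id,occasion_rank,days_before_survey,product_id,container_volume_ml,fullness,count,share``
  (multiple rows per occasion allowed; rank 1 = most recent).
* ``responses.csv`` —
  ``person_id,sex,prep_drank,check_drank,audit1m,audit3mv,dep1,dep2,dep3``
  with category tokens ``never|lt_monthly|monthly_1_3|weekly_1_3|most_days``,
  sex ``female|male`` and gate answers ``yes|no`` (``check_drank`` and the
  audit items may be empty where not asked).

Validation failures name the file and line they occurred on.
"""

from __future__ import annotations

import csv
import hashlib
import json
from collections import OrderedDict
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .audit import FrequencyCategory
from .cohort import CohortParams, ParticipantRecord, compose_beverages, default_catalog
from .consumption import (
    BeverageEntry,
    BeverageProduct,
    Catalog,
    DrinkingOccasion,
    occasion_total_drinks,
)
from .errors import ValidationError

PRODUCTS_HEADER = ["product_id", "name", "abv_percent"]
OCCASIONS_DRINKS_HEADER = ["person_id", "occasion_rank", "days_before_survey", "standard_drinks"]
OCCASIONS_BEVERAGE_HEADER = [
    "person_id", "occasion_rank", "days_before_survey",
    "product_id", "container_volume_ml", "fullness", "count", "share",
]
RESPONSES_HEADER = [
    "person_id", "sex", "prep_drank", "check_drank",
    "audit1m", "audit3mv", "dep1", "dep2", "dep3",
]


@dataclass(frozen=True)
class SurveyResponse:
    """One row of responses.csv, typed."""

    person_id: str
    sex: str
    prep_drank: bool
    check_drank: Optional[bool]
    audit1m: Optional[FrequencyCategory]
    audit3mv: Optional[FrequencyCategory]
    dep_ratings: Tuple[FrequencyCategory, FrequencyCategory, FrequencyCategory]


def _err(path, line, message):
    raise ValidationError(f"{path}:{line}: {message}")


def _check_header(path: Path, header, expected) -> None:
    if header != expected:
        _err(path, 1, f"header mismatch: expected {','.join(expected)}, got "
                      f"{','.join(header or [])}")


def _parse_float(path, line, field, value, lo=None, hi=None) -> float:
    try:
        x = float(value)
    except ValueError:
        _err(path, line, f"{field}: not a number: {value!r}")
    if lo is not None and x < lo:
        _err(path, line, f"{field}: must be >= {lo}, got {x}")
    if hi is not None and x > hi:
        _err(path, line, f"{field}: must be <= {hi}, got {x}")
    return x


def _parse_int(path, line, field, value, lo=None) -> int:
    try:
        x = int(value)
    except ValueError:
        _err(path, line, f"{field}: not an integer: {value!r}")
    if lo is not None and x < lo:
        _err(path, line, f"{field}: must be >= {lo}, got {x}")
    return x


def _parse_bool(path, line, field, value, allow_empty=False):
    if value == "":
        if allow_empty:
            return None
        _err(path, line, f"{field}: missing")
    if value not in ("yes", "no"):
        _err(path, line, f"{field}: expected yes|no, got {value!r}")
    return value == "yes"


def _parse_category(path, line, field, value, allow_empty=False):
    if value == "":
        if allow_empty:
            return None
        _err(path, line, f"{field}: missing")
    try:
        return FrequencyCategory.from_token(value)
    except ValidationError as exc:
        _err(path, line, f"{field}: {exc}")


def read_products(path) -> Dict[str, BeverageProduct]:
    """Read a product catalog; abv_percent becomes a fraction internally."""
    path = Path(path)
    catalog: Dict[str, BeverageProduct] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(path, header, PRODUCTS_HEADER)
        for line, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(PRODUCTS_HEADER):
                _err(path, line, f"expected {len(PRODUCTS_HEADER)} columns, got {len(row)}")
            product_id, name, abv_percent = row
            if product_id in catalog:
                _err(path, line, f"duplicate product_id {product_id!r}")
            abv = _parse_float(path, line, "abv_percent", abv_percent, lo=0.0, hi=100.0)
            try:
                catalog[product_id] = BeverageProduct(product_id, name, abv / 100.0)
            except ValidationError as exc:
                _err(path, line, str(exc))
    return catalog


def write_products(catalog: Catalog, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PRODUCTS_HEADER)
        for pid in sorted(catalog):
            p = catalog[pid]
            writer.writerow([p.product_id, p.name, repr(p.abv * 100.0)])


def detect_occasions_dialect(path) -> str:
    """'drinks' or 'beverage', from the header row."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh), None)
    if header == OCCASIONS_DRINKS_HEADER:
        return "drinks"
    if header == OCCASIONS_BEVERAGE_HEADER:
        return "beverage"
    raise ValidationError(
        f"{path}:1: header matches neither occasions dialect"
    )


def read_occasions(path) -> Dict[str, List[DrinkingOccasion]]:
    """Read occasions.csv in either dialect.

    Returns occasions per person sorted by occasion_rank (1 = most recent);
    in the beverage dialect, rows sharing (person_id, occasion_rank) merge
    into one occasion with several entries.
    """
    path = Path(path)
    dialect = detect_occasions_dialect(path)
    # person -> rank -> (days, entries-or-drinks)
    acc: Dict[str, "OrderedDict"] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader)  # header validated by detect
        for line, row in enumerate(reader, start=2):
            if not row:
                continue
            expected = OCCASIONS_DRINKS_HEADER if dialect == "drinks" else OCCASIONS_BEVERAGE_HEADER
            if len(row) != len(expected):
                _err(path, line, f"expected {len(expected)} columns, got {len(row)}")
            person_id = row[0]
            rank = _parse_int(path, line, "occasion_rank", row[1], lo=1)
            days = _parse_int(path, line, "days_before_survey", row[2], lo=0)
            person = acc.setdefault(person_id, OrderedDict())
            if dialect == "drinks":
                drinks = _parse_float(path, line, "standard_drinks", row[3], lo=0.0)
                if rank in person:
                    _err(path, line, f"duplicate (person_id, occasion_rank) = ({person_id}, {rank})")
                person[rank] = (days, drinks)
            else:
                entry = BeverageEntry(
                    product_id=row[3],
                    container_volume_ml=_parse_float(path, line, "container_volume_ml", row[4]),
                    fullness=_parse_float(path, line, "fullness", row[5], lo=0.0, hi=1.0),
                    count=_parse_float(path, line, "count", row[6], lo=0.0),
                    share=_parse_float(path, line, "share", row[7], lo=0.0, hi=1.0),
                )
                if rank in person:
                    prev_days, entries = person[rank]
                    if prev_days != days:
                        _err(path, line, f"occasion rank {rank} of {person_id} has "
                                         f"inconsistent days_before_survey ({prev_days} vs {days})")
                    entries.append(entry)
                else:
                    person[rank] = (days, [entry])
    result: Dict[str, List[DrinkingOccasion]] = {}
    for person_id, by_rank in acc.items():
        occasions = []
        for rank in sorted(by_rank):
            days, payload = by_rank[rank]
            if dialect == "drinks":
                occasions.append(DrinkingOccasion(days_before_survey=days, standard_drinks=payload))
            else:
                occasions.append(DrinkingOccasion(days_before_survey=days, entries=tuple(payload)))
        result[person_id] = occasions
    return result


def read_responses(path) -> List[SurveyResponse]:
    path = Path(path)
    responses: List[SurveyResponse] = []
    seen = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(path, header, RESPONSES_HEADER)
        for line, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(RESPONSES_HEADER):
                _err(path, line, f"expected {len(RESPONSES_HEADER)} columns, got {len(row)}")
            person_id = row[0]
            if person_id in seen:
                _err(path, line, f"duplicate person_id {person_id!r}")
            seen.add(person_id)
            sex = row[1]
            if sex not in ("female", "male"):
                _err(path, line, f"sex: expected female|male, got {sex!r}")
            prep = _parse_bool(path, line, "prep_drank", row[2])
            check = _parse_bool(path, line, "check_drank", row[3], allow_empty=True)
            if not prep and check is None:
                _err(path, line, "check_drank must be answered when prep_drank is no")
            responses.append(
                SurveyResponse(
                    person_id=person_id,
                    sex=sex,
                    prep_drank=prep,
                    check_drank=check,
                    audit1m=_parse_category(path, line, "audit1m", row[4], allow_empty=True),
                    audit3mv=_parse_category(path, line, "audit3mv", row[5], allow_empty=True),
                    dep_ratings=tuple(
                        _parse_category(path, line, f"dep{i}", row[5 + i])
                        for i in (1, 2, 3)
                    ),
                )
            )
    return responses


def _occasion_rows(person_id, occasions, dialect, catalog):
    for rank, occ in enumerate(occasions, start=1):
        if dialect == "drinks":
            drinks = occasion_total_drinks(occ, catalog)
            yield [person_id, rank, occ.days_before_survey, repr(float(drinks))]
        else:
            entries = occ.entries
            if entries is None:
                entries = compose_beverages(float(occ.standard_drinks), catalog)
            if not entries:  # zero-drink occasion: one empty container row
                pid = sorted(catalog)[0]
                entries = [BeverageEntry(pid, 375.0, fullness=0.0)]
            for e in entries:
                yield [
                    person_id, rank, occ.days_before_survey, e.product_id,
                    repr(e.container_volume_ml), repr(e.fullness),
                    repr(e.count), repr(e.share),
                ]


def write_occasions(
    occasions_by_person: Dict[str, Sequence[DrinkingOccasion]],
    path,
    dialect: str = "drinks",
    catalog: Optional[Catalog] = None,
) -> None:
    if dialect not in ("drinks", "beverage"):
        raise ValidationError(f"dialect must be drinks|beverage, got {dialect!r}")
    if catalog is None:
        catalog = default_catalog()
    header = OCCASIONS_DRINKS_HEADER if dialect == "drinks" else OCCASIONS_BEVERAGE_HEADER
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for person_id in sorted(occasions_by_person):
            for row in _occasion_rows(person_id, occasions_by_person[person_id], dialect, catalog):
                writer.writerow(row)


def write_responses(records: Sequence[ParticipantRecord], path) -> None:
    def token(cat):
        return "" if cat is None else cat.token

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESPONSES_HEADER)
        for r in sorted(records, key=lambda r: r.person_id):
            writer.writerow([
                r.person_id,
                r.sex,
                "yes" if r.prep_drank else "no",
                "" if r.check_drank is None else ("yes" if r.check_drank else "no"),
                token(r.audit1m),
                token(r.audit3mv),
                *[d.token for d in r.dependence_ratings],
            ])


def write_cohort(
    records: Sequence[ParticipantRecord],
    out_dir,
    dialect: str = "drinks",
    catalog: Optional[Catalog] = None,
    params: Optional[CohortParams] = None,
    seed: Optional[int] = None,
) -> Dict[str, Path]:
    """Write a generated cohort as products/occasions/responses CSV plus a
    provenance JSON (parameters, seed, content hashes)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if catalog is None:
        catalog = default_catalog()
    paths = {
        "products": out_dir / "products.csv",
        "occasions": out_dir / "occasions.csv",
        "responses": out_dir / "responses.csv",
    }
    write_products(catalog, paths["products"])
    write_occasions(
        {r.person_id: r.occasions for r in records if r.occasions},
        paths["occasions"],
        dialect=dialect,
        catalog=catalog,
    )
    write_responses(records, paths["responses"])
    hashes = {
        name: hashlib.sha256(p.read_bytes()).hexdigest() for name, p in paths.items()
    }
    provenance = {
        "params": asdict(params) if params is not None else None,
        "seed": seed,
        "dialect": dialect,
        "n_records": len(records),
        "content_sha256": hashes,
    }
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2) + "\n", encoding="utf-8")
    paths["provenance"] = prov_path
    return paths
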