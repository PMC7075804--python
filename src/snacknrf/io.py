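"""Product-table CSV reading and writing.

Schema (per-100 g basis, US units; ingredient text is quoted because it
contains commas)::

    product_id,name,country,wweia_code,energy_kcal_100g,
    protein_g_100g,fiber_g_100g,vitamin_a_ug_100g,vitamin_c_mg_100g,
    vitamin_d_ug_100g,calcium_mg_100g,iron_mg_100g,potassium_mg_100g,
    satfat_g_100g,total_sugar_g_100g,added_sugar_g_100g,sodium_mg_100g,
    ingredient_text

``serving_size_g`` is optional; unknown columns are preserved on
round-trip.  Blank nutrient cells become missing values that score as 0
with a warning downstream.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import RowValidationError, SchemaError
from .scoring import ProductRecord

SCHEMA_VERSION = "1.0"

#: CSV column -> internal nutrient key
NUTRIENT_COLUMNS: dict[str, str] = {
    "protein_g_100g": "protein",
    "fiber_g_100g": "fiber",
    "vitamin_a_ug_100g": "vitamin_a",
    "vitamin_c_mg_100g": "vitamin_c",
    "vitamin_d_ug_100g": "vitamin_d",
    "calcium_mg_100g": "calcium",
    "iron_mg_100g": "iron",
    "potassium_mg_100g": "potassium",
    "satfat_g_100g": "saturated_fat",
    "added_sugar_g_100g": "added_sugar",
    "sodium_mg_100g": "sodium",
}

MANDATORY_COLUMNS: tuple[str, ...] = (
    "product_id",
    "name",
    "country",
    "wweia_code",
    "energy_kcal_100g",
    *NUTRIENT_COLUMNS,
    "total_sugar_g_100g",
    "ingredient_text",
)

OPTIONAL_COLUMNS: tuple[str, ...] = ("serving_size_g",)


@dataclass
class ProductTable:
    """An ordered product list with provenance metadata and any unknown
    CSV columns carried along for round-tripping."""

    records: list[ProductRecord]
    source_path: str | None = None
    schema_version: str = SCHEMA_VERSION
    extra_columns: pd.DataFrame | None = None

    def __post_init__(self):
        ids = [r.product_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RowValidationError(
                [(0, f"duplicate product_id(s): {', '.join(dupes)}")]
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _cell(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_products(path: str | Path) -> ProductTable:
    """Read and validate a product CSV.

    Row-level validation failures (negative amounts, added sugar above
    total sugar, bad country codes) are collected and reported together
    with their CSV line numbers; a missing mandatory column raises
    :class:`~snacknrf.errors.SchemaError` immediately.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    known = set(MANDATORY_COLUMNS) | set(OPTIONAL_COLUMNS)
    extra = [c for c in df.columns if c not in known]

    records: list[ProductRecord] = []
    failures: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            nutrients = {
                key: _cell(row[col]) for col, key in NUTRIENT_COLUMNS.items()
            }
            records.append(
                ProductRecord(
                    product_id=str(row["product_id"]),
                    name=str(row["name"]),
                    country=str(row["country"]),
                    wweia_code=int(row["wweia_code"]),
                    energy_per_100g=float(row["energy_kcal_100g"]),
                    nutrients_per_100g=nutrients,
                    total_sugar_per_100g=_cell(row["total_sugar_g_100g"]),
                    ingredient_text=str(row["ingredient_text"]),
                    serving_size_g=_cell(row["serving_size_g"])
                    if "serving_size_g" in df.columns
                    else None,
                )
            )
        except (ValueError, TypeError) as exc:
            failures.append((line_no, str(exc)))
    if failures:
        raise RowValidationError(failures)
    return ProductTable(
        records=records,
        source_path=str(path),
        extra_columns=df[extra].copy() if extra else None,
    )


def products_to_frame(records: Iterable[ProductRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "product_id": r.product_id,
            "name": r.name,
            "country": r.country,
            "wweia_code": r.wweia_code,
            "energy_kcal_100g": r.energy_per_100g,
        }
        for col, key in NUTRIENT_COLUMNS.items():
            row[col] = r.nutrients_per_100g.get(key)
        row["total_sugar_g_100g"] = r.total_sugar_per_100g
        row["ingredient_text"] = r.ingredient_text
        if r.serving_size_g is not None:
            row["serving_size_g"] = r.serving_size_g
        rows.append(row)
    return pd.DataFrame(rows)


def write_products(table: ProductTable | list[ProductRecord],
                   path: str | Path) -> None:
    """Write products back to the CSV schema (round-trip stable)."""
    records = table.records if isinstance(table, ProductTable) else table
    df = products_to_frame(records)
    if isinstance(table, ProductTable) and table.extra_columns is not None:
        for col in table.extra_columns.columns:
            df[col] = table.extra_columns[col].to_numpy()
    # %.17g round-trips IEEE doubles exactly (read-write-read fixpoint)
    df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL, float_format="%.17g")
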