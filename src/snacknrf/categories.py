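"""WWEIA category assignment, category summary tables, and two-group
comparisons.

Products are binned into 24 What We Eat in America (WWEIA) snack
categories by their 4-digit category code; summaries report per-category
n, mean, and sample SD of energy density, the LIM sub-score, and the
NRF8.3 score, plus an overall row with n-weighted means.  Group
comparisons contrast two product subsets (e.g. fruit-or-dairy-first vs
neither) on each %DV, %MRV, energy density, and the three scores, with
one-way ANOVA p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateGroupError,
    EmptySummaryError,
    UnknownCategoryError,
)
from .scoring import ProductRecord, ScoreResult

#: Order of the per-variable rows in a group-comparison table: the eight
#: qualifying %DVs, the four %MRVs (total sugar reported but outside LIM),
#: energy density, and the three scores.
COMPARISON_VARIABLES: tuple[str, ...] = (
    "pct_dv_protein",
    "pct_dv_fiber",
    "pct_dv_vitamin_a",
    "pct_dv_vitamin_c",
    "pct_dv_vitamin_d",
    "pct_dv_calcium",
    "pct_dv_iron",
    "pct_dv_potassium",
    "pct_mrv_saturated_fat",
    "pct_mrv_total_sugar",
    "pct_mrv_added_sugar",
    "pct_mrv_sodium",
    "energy_density",
    "nr_subscore",
    "lim_subscore",
    "nrf_score",
)


@dataclass(frozen=True)
class WweiaCategory:
    """One WWEIA snack category: a label and its set of 4-digit codes."""

    row_index: int
    label: str
    codes: frozenset[int]


class CategoryMap:
    """The 24-category WWEIA snack map with disjoint code sets."""

    def __init__(self, categories: Sequence[WweiaCategory]):
        self.categories = tuple(sorted(categories, key=lambda c: c.row_index))
        self._by_code: dict[int, WweiaCategory] = {}
        for cat in self.categories:
            for code in cat.codes:
                if code in self._by_code:
                    raise ValueError(
                        f"WWEIA code {code} appears in more than one category"
                    )
                self._by_code[code] = cat

    @classmethod
    def from_csv(cls, path: str | Path) -> "CategoryMap":
        df = pd.read_csv(path)
        cats = [
            WweiaCategory(
                row_index=int(row.row_index),
                label=str(row.label),
                codes=frozenset(int(c) for c in str(row.codes).split(";")),
            )
            for row in df.itertuples()
        ]
        return cls(cats)

    @classmethod
    def default(cls) -> "CategoryMap":
        path = resources.files("snacknrf.data").joinpath("wweia_categories.csv")
        return cls.from_csv(path)  # type: ignore[arg-type]

    def assign(self, wweia_code: int) -> WweiaCategory:
        try:
            return self._by_code[int(wweia_code)]
        except KeyError:
            raise UnknownCategoryError(int(wweia_code)) from None

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self):
        return iter(self.categories)


def assign_category(
    wweia_code: int, category_map: CategoryMap | None = None
) -> WweiaCategory:
    """Return the unique category containing ``wweia_code``."""
    return (category_map or CategoryMap.default()).assign(wweia_code)


@dataclass
class CategorySummary:
    category: WweiaCategory
    n: int
    ed_mean: float
    ed_sd: float
    lim_mean: float
    lim_sd: float
    nrf_mean: float
    nrf_sd: float


def _sd(values: np.ndarray) -> float:
    # sample SD (n-1 denominator); 0 for a single observation
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def summarize_categories(
    products: Sequence[ProductRecord],
    scores: Sequence[ScoreResult],
    category_map: CategoryMap | None = None,
) -> tuple[list[CategorySummary], CategorySummary]:
    """Per-category n/mean/SD of ED, LIM, and NRF, plus an overall row.

    The overall row carries the pooled n and the n-weighted means (which
    equal the plain pooled means over all products).
    """
    if not products:
        raise EmptySummaryError("no products to summarize")
    if len(products) != len(scores):
        raise ValueError("products and scores must be parallel sequences")
    cmap = category_map or CategoryMap.default()

    df = pd.DataFrame(
        {
            "row_index": [cmap.assign(p.wweia_code).row_index for p in products],
            "ed": [s.energy_density for s in scores],
            "lim": [s.lim_subscore for s in scores],
            "nrf": [s.nrf_score for s in scores],
        }
    )
    by_row = {c.row_index: c for c in cmap}
    summaries: list[CategorySummary] = []
    for row_index, grp in df.groupby("row_index", sort=True):
        summaries.append(
            CategorySummary(
                category=by_row[int(row_index)],
                n=len(grp),
                ed_mean=float(grp.ed.mean()),
                ed_sd=_sd(grp.ed.to_numpy()),
                lim_mean=float(grp.lim.mean()),
                lim_sd=_sd(grp.lim.to_numpy()),
                nrf_mean=float(grp.nrf.mean()),
                nrf_sd=_sd(grp.nrf.to_numpy()),
            )
        )
    overall = CategorySummary(
        category=WweiaCategory(row_index=0, label="Total", codes=frozenset()),
        n=len(df),
        ed_mean=float(df.ed.mean()),
        ed_sd=_sd(df.ed.to_numpy()),
        lim_mean=float(df.lim.mean()),
        lim_sd=_sd(df.lim.to_numpy()),
        nrf_mean=float(df.nrf.mean()),
        nrf_sd=_sd(df.nrf.to_numpy()),
    )
    return summaries, overall


def summaries_to_frame(
    summaries: list[CategorySummary], overall: CategorySummary | None = None
) -> pd.DataFrame:
    """Render category summaries as a table (2-decimal rounding applied
    at presentation time only)."""
    rows = []
    for s in summaries + ([overall] if overall is not None else []):
        rows.append(
            {
                "row_index": s.category.row_index,
                "category": s.category.label,
                "n": s.n,
                "ed_mean": round(s.ed_mean, 2),
                "ed_sd": round(s.ed_sd, 2),
                "lim_mean": round(s.lim_mean, 2),
                "lim_sd": round(s.lim_sd, 2),
                "nrf_mean": round(s.nrf_mean, 2),
                "nrf_sd": round(s.nrf_sd, 2),
            }
        )
    return pd.DataFrame(rows)


def scores_to_frame(scores: Sequence[ScoreResult]) -> pd.DataFrame:
    """Flatten ScoreResults into one row per product with the
    :data:`COMPARISON_VARIABLES` columns."""
    rows = []
    for s in scores:
        row: dict[str, float | str | None] = {"product_id": s.product_id}
        for nutrient, value in s.pct_dv_per_100kcal.items():
            row[f"pct_dv_{nutrient}"] = value
        for nutrient, value in s.pct_mrv_per_100kcal.items():
            row[f"pct_mrv_{nutrient}"] = value
        row["pct_mrv_total_sugar"] = s.total_sugar_pct_mrv
        row["energy_density"] = s.energy_density
        row["nr_subscore"] = s.nr_subscore
        row["lim_subscore"] = s.lim_subscore
        row["nrf_score"] = s.nrf_score
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ComparisonRow:
    variable: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    p_value: float


@dataclass
class GroupComparison:
    grouping_name: str
    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    rows: list[ComparisonRow]

    def to_frame(self, decimals: int | None = 2) -> pd.DataFrame:
        """Presentation table with significance labels mirroring the
        <0.05 / <0.001 reporting convention; raw p is always kept."""
        records = []
        for r in self.rows:
            if r.p_value < 0.001:
                sig = "<0.001"
            elif r.p_value < 0.05:
                sig = "<0.05"
            else:
                sig = f"{r.p_value:.3f}"
            rec = {
                "variable": r.variable,
                f"mean_{self.group_a_label}": r.mean_a,
                f"sem_{self.group_a_label}": r.sem_a,
                f"mean_{self.group_b_label}": r.mean_b,
                f"sem_{self.group_b_label}": r.sem_b,
                "p_value": r.p_value,
                "p_label": sig,
            }
            records.append(rec)
        df = pd.DataFrame(records)
        if decimals is not None:
            numeric = [c for c in df.columns if c.startswith(("mean_", "sem_"))]
            df[numeric] = df[numeric].round(decimals)
        return df


def _sem(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def compare_groups(
    scores: Sequence[ScoreResult],
    group_flag: Sequence[bool],
    grouping_name: str,
    group_a_label: str = "group_a",
    group_b_label: str = "group_b",
    variables: Sequence[str] = COMPARISON_VARIABLES,
) -> GroupComparison:
    """Compare flagged vs unflagged products on each variable.

    For every variable the group means, SEMs (SD/sqrt(n)), and the one-way
    ANOVA p-value across the two groups are reported.  With two groups the
    one-way ANOVA F equals the square of the pooled-variance t statistic.
    """
    if len(scores) != len(group_flag):
        raise ValueError("scores and group_flag must be parallel sequences")
    df = scores_to_frame(scores)
    flag = np.asarray(group_flag, dtype=bool)
    n_a, n_b = int(flag.sum()), int((~flag).sum())
    if n_a < 2 or n_b < 2:
        raise DegenerateGroupError(
            f"both groups need >= 2 products (got {n_a} and {n_b}); "
            "SEM and ANOVA are undefined otherwise"
        )
    rows: list[ComparisonRow] = []
    for var in variables:
        if var not in df.columns or df[var].isna().any():
            raise ValueError(f"variable {var!r} missing for some products")
        a = df.loc[flag, var].to_numpy(dtype=float)
        b = df.loc[~flag, var].to_numpy(dtype=float)
        if np.allclose(a.var(), 0) and np.allclose(b.var(), 0) and np.isclose(
            a.mean(), b.mean()
        ):
            p = 1.0  # no variance anywhere: F = 0/0, conventionally no effect
        else:
            _, p = stats.f_oneway(a, b)
            if np.isnan(p):  # zero between-group variance
                p = 1.0
        rows.append(
            ComparisonRow(
                variable=var,
                mean_a=float(a.mean()),
                sem_a=_sem(a),
                mean_b=float(b.mean()),
                sem_b=_sem(b),
                p_value=float(p),
            )
        )
    return GroupComparison(
        grouping_name=grouping_name,
        group_a_label=group_a_label,
        group_b_label=group_b_label,
        n_a=n_a,
        n_b=n_b,
        rows=rows,
    )
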