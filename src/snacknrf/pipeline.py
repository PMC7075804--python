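"""End-to-end pipeline: score -> classify -> summarize -> compare -> plot.

Given a product table the pipeline scores every product on the 100-kcal
basis (skipping unscorable ones with a logged warning), classifies every
ingredient label, builds the category summary table, runs both group
contrasts (fruit-or-dairy-first vs neither; FVN vs no FVN), and
optionally writes presentation CSVs plus four scatterplots: energy
density vs NRF8.3 and LIM vs NR8, each category-aggregated and
per-product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .categories import (
    CategoryMap,
    CategorySummary,
    GroupComparison,
    compare_groups,
    scores_to_frame,
    summaries_to_frame,
    summarize_categories,
)
from .errors import DegenerateGroupError, UnscorableProductError
from .ingredients import IngredientClassification, classify_ingredients
from .io import ProductTable
from .scoring import ProductRecord, ReferenceStandards, ScoreResult, score_product

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    products: list[ProductRecord]
    scores: list[ScoreResult]
    classifications: list[IngredientClassification]
    category_summaries: list[CategorySummary]
    overall_summary: CategorySummary
    comparisons: dict[str, GroupComparison]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def flags_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "product_id": [p.product_id for p in self.products],
                "dairy_first": [c.dairy_first for c in self.classifications],
                "fruit_first": [c.fruit_first for c in self.classifications],
                "fruit_or_dairy_first": [
                    c.fruit_or_dairy_first for c in self.classifications
                ],
                "fvn": [c.fvn_present for c in self.classifications],
            }
        )

    def summary_counts(self) -> dict[str, int]:
        flags = self.flags_frame()
        return {
            "scored": len(self.scores),
            "skipped": len(self.skipped),
            "dairy_first": int(flags.dairy_first.sum()),
            "fruit_first": int(flags.fruit_first.sum()),
            "fruit_or_dairy_first": int(flags.fruit_or_dairy_first.sum()),
            "fvn": int(flags.fvn.sum()),
        }


def run_pipeline(
    table: ProductTable | list[ProductRecord],
    standards: ReferenceStandards | None = None,
    category_map: CategoryMap | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on ``table``; write tables and figures to
    ``out_dir`` when given.  Stage failures are re-raised with the stage
    name attached."""
    records = list(table)
    standards = standards or ReferenceStandards()
    cmap = category_map or CategoryMap.default()

    scored_products: list[ProductRecord] = []
    scores: list[ScoreResult] = []
    skipped: list[tuple[str, str]] = []
    for product in records:
        try:
            scores.append(score_product(product, standards))
            scored_products.append(product)
        except UnscorableProductError as exc:
            logger.warning("scoring: skipping %s: %s", product.product_id, exc)
            skipped.append((product.product_id, str(exc)))

    try:
        classifications = [
            classify_ingredients(p.ingredient_text, p.wweia_code)
            for p in scored_products
        ]
    except Exception as exc:
        raise type(exc)(f"classify stage: {exc}") from exc

    try:
        summaries, overall = summarize_categories(scored_products, scores, cmap)
    except Exception as exc:
        raise type(exc)(f"summarize stage: {exc}") from exc

    flags = pd.DataFrame(
        {
            "fruit_or_dairy_first": [c.fruit_or_dairy_first for c in classifications],
            "fvn": [c.fvn_present for c in classifications],
        }
    )
    comparisons: dict[str, GroupComparison] = {}
    contrasts = (
        ("first_ingredient", flags.fruit_or_dairy_first, "fruit_or_dairy",
         "neither"),
        ("fvn", flags.fvn, "fvn", "no_fvn"),
    )
    for name, flag_col, label_a, label_b in contrasts:
        try:
            comparisons[name] = compare_groups(
                scores,
                flag_col.tolist(),
                grouping_name=name,
                group_a_label=label_a,
                group_b_label=label_b,
            )
        except DegenerateGroupError as exc:
            # one-sided datasets (e.g. all-dairy subsets) have no contrast
            logger.warning("compare stage: skipping %s contrast: %s", name, exc)
        except Exception as exc:
            raise type(exc)(f"compare stage: {exc}") from exc

    result = PipelineResult(
        products=scored_products,
        scores=scores,
        classifications=classifications,
        category_summaries=summaries,
        overall_summary=overall,
        comparisons=comparisons,
        skipped=skipped,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    counts = result.summary_counts()
    logger.info(
        "pipeline: %d scored, %d skipped; %d fruit-or-dairy-first, %d FVN",
        counts["scored"],
        counts["skipped"],
        counts["fruit_or_dairy_first"],
        counts["fvn"],
    )
    return result


# ---------------------------------------------------------------------------
# Output rendering
# ---------------------------------------------------------------------------


def _category_points(result: PipelineResult) -> pd.DataFrame:
    df = scores_to_frame(result.scores)
    cmap = CategoryMap.default()
    df["category"] = [
        cmap.assign(p.wweia_code).label for p in result.products
    ]
    agg = df.groupby("category").agg(
        n=("product_id", "size"),
        ed=("energy_density", "mean"),
        nr=("nr_subscore", "mean"),
        lim=("lim_subscore", "mean"),
        nrf=("nrf_score", "mean"),
    )
    return agg.reset_index()


def _scatter(ax, x, y, sizes=None, labels=None):
    ax.scatter(x, y, s=sizes if sizes is not None else 18, alpha=0.6,
               edgecolor="k", linewidth=0.3)
    if labels is not None:
        for xi, yi, lab in zip(x, y, labels):
            ax.annotate(lab, (xi, yi), fontsize=5, alpha=0.8)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write category/comparison CSVs and the four scatterplots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = out / "category_summary.csv"
    summaries_to_frame(result.category_summaries, result.overall_summary).to_csv(
        path, index=False
    )
    written.append(path)

    for name, comparison in result.comparisons.items():
        path = out / f"comparison_{name}.csv"
        comparison.to_frame().to_csv(path, index=False)
        written.append(path)

    path = out / "product_scores.csv"
    scores_to_frame(result.scores).round(4).to_csv(path, index=False)
    written.append(path)

    path = out / "ingredient_flags.csv"
    result.flags_frame().to_csv(path, index=False)
    written.append(path)

    per_product = scores_to_frame(result.scores)
    agg = _category_points(result)
    panels = [
        ("fig_category_ed_vs_nrf.png", agg.nrf, agg.ed, 12 * agg.n, agg.category,
         "NRF8.3 score per 100 kcal", "Energy density (kcal/100 g)"),
        ("fig_category_lim_vs_nr.png", agg.nr, agg.lim, 12 * agg.n, agg.category,
         "NR8 subscore per 100 kcal", "LIM subscore per 100 kcal"),
        ("fig_product_ed_vs_nrf.png", per_product.nrf_score,
         per_product.energy_density, None, None,
         "NRF8.3 score per 100 kcal", "Energy density (kcal/100 g)"),
        ("fig_product_lim_vs_nr.png", per_product.nr_subscore,
         per_product.lim_subscore, None, None,
         "NR8 subscore per 100 kcal", "LIM subscore per 100 kcal"),
    ]
    for fname, x, y, sizes, labels, xlabel, ylabel in panels:
        fig, ax = plt.subplots(figsize=(6, 5))
        _scatter(ax, x, y, sizes, labels)
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        path = out / fname
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
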