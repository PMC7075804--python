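"""Tests for WWEIA category assignment, summaries, and group comparisons."""

import numpy as np
import pytest
from scipy import stats

from snacknrf import (
    CategoryMap,
    ProductRecord,
    assign_category,
    compare_groups,
    score_product,
    summarize_categories,
)
from snacknrf.categories import COMPARISON_VARIABLES, scores_to_frame
from snacknrf.errors import (
    DegenerateGroupError,
    EmptySummaryError,
    UnknownCategoryError,
)


def simple_product(pid, code, ed, sugar):
    return ProductRecord(
        product_id=pid,
        name=pid,
        country="US",
        wweia_code=code,
        energy_per_100g=ed,
        nutrients_per_100g={"added_sugar": sugar},
        total_sugar_per_100g=sugar,
        ingredient_text="sugar",
    )


class TestAssignCategory:
    @pytest.mark.parametrize(
        "code,label",
        [
            (1802, "Yogurt, whole/reduced"),
            (5704, "Candy, fruit"),
            (1004, "Low fat milk, plain and flavored"),
            (7204, "Fruit based soft drinks"),
        ],
    )
    def test_known_codes(self, code, label):
        assert assign_category(code).label == label

    def test_unknown_code_raises(self):
        with pytest.raises(UnknownCategoryError) as exc:
            assign_category(9999)
        assert "9999" in str(exc.value)

    def test_map_has_24_disjoint_categories(self):
        cmap = CategoryMap.default()
        assert len(cmap) == 24
        all_codes = [code for cat in cmap for code in cat.codes]
        assert len(all_codes) == len(set(all_codes))
        assert [c.row_index for c in cmap] == list(range(1, 25))


class TestSummaries:
    def test_two_point_mean_and_single_product_sd(self, standards):
        products = [
            simple_product("A", 5502, 100, 5),   # LIM 10
            simple_product("B", 5502, 100, 10),  # LIM 20
            simple_product("C", 1602, 200, 0),
        ]
        scores = [score_product(p, standards) for p in products]
        summaries, overall = summarize_categories(products, scores)
        by_label = {s.category.label: s for s in summaries}
        cakes = by_label["Cakes, cookies, brownies"]
        assert cakes.n == 2
        assert cakes.lim_mean == pytest.approx(15.0)
        cheese = by_label["Cheese"]
        assert cheese.n == 1
        assert cheese.ed_sd == 0.0
        assert overall.n == 3

    def test_partition_and_weighted_mean_identity(
        self, default_dataset, default_pipeline_result
    ):
        """Category counts partition the dataset and the n-weighted mean of
        category means equals the pooled mean exactly."""
        res = default_pipeline_result
        ns = [s.n for s in res.category_summaries]
        assert sum(ns) == len(res.products) == res.overall_summary.n
        for attr in ("ed_mean", "lim_mean", "nrf_mean"):
            weighted = sum(
                getattr(s, attr) * s.n for s in res.category_summaries
            ) / sum(ns)
            assert weighted == pytest.approx(
                getattr(res.overall_summary, attr), rel=1e-12
            )

    def test_empty_input_rejected(self):
        with pytest.raises(EmptySummaryError):
            summarize_categories([], [])


class TestCompareGroups:
    def _scores(self, standards, sugars, codes=None):
        products = [
            simple_product(f"P{i}", 5502 if codes is None else codes[i], 100, s)
            for i, s in enumerate(sugars)
        ]
        return [score_product(p, standards) for p in products]

    def test_identical_groups_give_p_one(self, standards):
        scores = self._scores(standards, [1, 2, 3, 1, 2, 3])
        flags = [True, True, True, False, False, False]
        comparison = compare_groups(
            scores, flags, "test", variables=["lim_subscore"]
        )
        assert comparison.rows[0].p_value == pytest.approx(1.0)

    def test_sem_is_sd_over_sqrt_n(self, standards):
        # nine values with SD exactly 3.0 -> SEM 1.0
        base = np.array([-4, -3, -2, -1, 0, 1, 2, 3, 4], dtype=float)
        values = base * (3.0 / np.std(base, ddof=1))
        scores = self._scores(standards, list(values + 10) + [1, 2])
        flags = [True] * 9 + [False] * 2
        comparison = compare_groups(
            scores, flags, "test", variables=["pct_mrv_added_sugar"]
        )
        # %MRV at ED 100 is 2x the gram amount
        assert comparison.rows[0].sem_a == pytest.approx(2.0)

    def test_anova_f_equals_t_squared(self, standards, rng):
        """For two groups the one-way ANOVA p equals the two-sided
        pooled-variance t-test p (F = t^2)."""
        for _ in range(20):
            a = rng.normal(10, 3, size=rng.integers(3, 20))
            b = rng.normal(12, 3, size=rng.integers(3, 20))
            f_stat, p_f = stats.f_oneway(a, b)
            t_stat, p_t = stats.ttest_ind(a, b, equal_var=True)
            assert f_stat == pytest.approx(t_stat**2, rel=1e-9)
            assert p_f == pytest.approx(p_t, rel=1e-9)

    def test_anova_matches_permutation_null(self, standards, rng):
        """The ANOVA p agrees with a 10,000-draw permutation p within
        Monte-Carlo error on small random datasets."""
        n_perm = 10_000
        for _ in range(3):
            a = rng.normal(10, 3, size=12)
            b = rng.normal(11.5, 3, size=15)
            _, p_anova = stats.f_oneway(a, b)
            pooled = np.concatenate([a, b])
            observed = abs(a.mean() - b.mean())
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                count += abs(perm[:12].mean() - perm[12:].mean()) >= observed
            p_perm = (count + 1) / (n_perm + 1)
            mc_err = 3 * np.sqrt(p_anova * (1 - p_anova) / n_perm)
            assert abs(p_perm - p_anova) < max(mc_err, 0.02)

    def test_degenerate_group_rejected(self, standards):
        scores = self._scores(standards, [1, 2, 3])
        with pytest.raises(DegenerateGroupError):
            compare_groups(scores, [True, False, False], "test")

    def test_group_sizes_partition_dataset(self, default_pipeline_result):
        res = default_pipeline_result
        for comparison in res.comparisons.values():
            assert comparison.n_a + comparison.n_b == len(res.products)

    def test_nr_and_lim_rows_are_component_sums(self, default_pipeline_result):
        """In any comparison table the NR row equals the sum of the eight
        %DV rows and the LIM row the sum of the three limiting %MRV rows."""
        for comparison in default_pipeline_result.comparisons.values():
            rows = {r.variable: r for r in comparison.rows}
            for side in ("mean_a", "mean_b"):
                nr_sum = sum(
                    getattr(rows[v], side)
                    for v in COMPARISON_VARIABLES
                    if v.startswith("pct_dv_")
                )
                lim_sum = sum(
                    getattr(rows[f"pct_mrv_{n}"], side)
                    for n in ("saturated_fat", "added_sugar", "sodium")
                )
                assert getattr(rows["nr_subscore"], side) == pytest.approx(
                    nr_sum, rel=1e-9
                )
                assert getattr(rows["lim_subscore"], side) == pytest.approx(
                    lim_sum, rel=1e-9
                )

    def test_significance_labels(self, standards, rng):
        scores = self._scores(standards, list(rng.uniform(0, 10, 12)))
        flags = [True] * 6 + [False] * 6
        frame = compare_groups(
            scores, flags, "test", variables=["lim_subscore"]
        ).to_frame()
        assert {"p_value", "p_label"} <= set(frame.columns)
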