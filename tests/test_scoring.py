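"""Unit and property tests for the NRFn.3 scoring core."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snacknrf import (
    ED_MIN,
    ProductRecord,
    ReferenceStandards,
    UnscorableProductError,
    amount_per_100kcal,
    energy_density,
    percent_dv,
    percent_mrv,
    score_product,
)
from snacknrf.errors import ConfigurationError, InvalidInputError

from conftest import random_product


def make_product(ed=100.0, total_sugar=None, **nutrients):
    return ProductRecord(
        product_id="T1",
        name="test",
        country="US",
        wweia_code=5502,
        energy_per_100g=ed,
        nutrients_per_100g=nutrients,
        total_sugar_per_100g=total_sugar,
        ingredient_text="sugar",
    )


class TestEnergyDensity:
    @pytest.mark.parametrize(
        "kcal,grams,expected",
        [(59, 100, 59), (150, 50, 300), (0, 100, 0)],
    )
    def test_values(self, kcal, grams, expected):
        assert energy_density(kcal, grams) == pytest.approx(expected)

    @pytest.mark.parametrize("grams", [0, -5])
    def test_nonpositive_mass_rejected(self, grams):
        with pytest.raises(InvalidInputError):
            energy_density(100, grams)


class TestPer100Kcal:
    @pytest.mark.parametrize(
        "amount,ed,expected", [(2, 100, 2), (3, 50, 6), (10, 500, 2)]
    )
    def test_values(self, amount, ed, expected):
        assert amount_per_100kcal(amount, ed) == pytest.approx(expected)

    def test_below_ed_min_names_product(self):
        with pytest.raises(UnscorableProductError) as exc:
            amount_per_100kcal(2.0, 0.5, product_id="P77")
        assert "P77" in str(exc.value)


class TestPercentDV:
    @pytest.mark.parametrize(
        "nutrient,amount,capped,uncapped",
        [
            ("protein", 50.0, 100.0, 100.0),
            ("vitamin_c", 160.0, 100.0, 200.0),
            ("fiber", 1.4, 5.0, 5.0),
        ],
    )
    def test_values(self, standards, nutrient, amount, capped, uncapped):
        assert percent_dv(nutrient, amount, standards) == (
            pytest.approx(capped),
            pytest.approx(uncapped),
        )

    def test_unknown_nutrient(self, standards):
        with pytest.raises(ConfigurationError):
            percent_dv("caffeine", 1.0, standards)


class TestPercentMRV:
    @pytest.mark.parametrize(
        "nutrient,amount,expected",
        [
            ("added_sugar", 25.0, 50.0),
            ("sodium", 0.0, 0.0),
            ("saturated_fat", 20.0, 100.0),
            ("saturated_fat", 40.0, 200.0),  # limiting side is never capped
        ],
    )
    def test_values(self, standards, nutrient, amount, expected):
        assert percent_mrv(nutrient, amount, standards) == pytest.approx(expected)

    def test_total_sugar_reference(self, standards):
        assert percent_mrv("total_sugar", 25.0, standards) == pytest.approx(50.0)

    def test_unknown_nutrient(self, standards):
        with pytest.raises(ConfigurationError):
            percent_mrv("trans_fat", 1.0, standards)


class TestScoreProduct:
    def test_null_food_scores_zero(self, standards):
        nutrients = {k: 0.0 for k in (*standards.qualifying, *standards.limiting)}
        result = score_product(make_product(total_sugar=0.0, **nutrients), standards)
        assert result.nr_subscore == 0
        assert result.lim_subscore == 0
        assert result.nrf_score == 0

    def test_full_dv_product_hits_cap_times_n(self, standards):
        # exactly one DV of everything per 100 kcal at ED 100 => NR = 800
        nutrients = {k: dv for k, (dv, _) in standards.qualifying.items()}
        nutrients.update({k: 0.0 for k in standards.limiting})
        result = score_product(make_product(ed=100.0, **nutrients), standards)
        assert result.nrf_score == pytest.approx(800.0)

    def test_missing_nutrients_contribute_zero_with_warning(
        self, standards, caplog
    ):
        with caplog.at_level(logging.WARNING, logger="snacknrf.scoring"):
            result = score_product(make_product(protein=5.0), standards)
        assert result.pct_dv_per_100kcal["fiber"] == 0.0
        assert result.pct_mrv_per_100kcal["sodium"] == 0.0
        assert any("missing" in rec.message for rec in caplog.records)

    def test_unscorable_energy_density(self, standards):
        with pytest.raises(UnscorableProductError):
            score_product(make_product(ed=0.2), standards)

    def test_total_sugar_excluded_from_lim(self, standards):
        product = make_product(
            ed=100.0, added_sugar=10.0, saturated_fat=0.0, sodium=0.0,
            total_sugar=30.0,
        )
        result = score_product(product, standards)
        assert result.lim_subscore == pytest.approx(20.0)  # added sugar only
        assert result.total_sugar_pct_mrv == pytest.approx(60.0)


class TestReferenceStandards:
    def test_yaml_round_trip(self, standards, tmp_path):
        path = tmp_path / "std.yaml"
        standards.to_yaml(path)
        loaded = ReferenceStandards.from_yaml(path)
        assert loaded == standards

    def test_shipped_config_matches_defaults(self):
        from importlib import resources

        path = resources.files("snacknrf.data").joinpath("standards_nrf8.3.yaml")
        assert ReferenceStandards.from_yaml(path) == ReferenceStandards()

    def test_qualifying_size_bounds(self):
        with pytest.raises(ConfigurationError):
            ReferenceStandards(qualifying={})
        too_many = {f"n{i}": (1.0, "g") for i in range(16)}
        with pytest.raises(ConfigurationError):
            ReferenceStandards(qualifying=too_many)

    def test_nrf6_variant(self, standards):
        six = dict(list(standards.qualifying.items())[:6])
        variant = ReferenceStandards(qualifying=six)
        nutrients = {k: dv for k, (dv, _) in six.items()}
        nutrients.update({k: 0.0 for k in variant.limiting})
        result = score_product(make_product(**nutrients), variant)
        assert result.nrf_score == pytest.approx(600.0)

    def test_negative_dv_rejected(self):
        with pytest.raises(ConfigurationError):
            ReferenceStandards(qualifying={"protein": (-1.0, "g")})


class TestRecordInvariants:
    def test_added_sugar_cannot_exceed_total(self):
        with pytest.raises(InvalidInputError):
            make_product(added_sugar=10.0, total_sugar=5.0)

    def test_negative_nutrient_rejected(self):
        with pytest.raises(InvalidInputError):
            make_product(protein=-1.0)

    def test_unknown_country_rejected(self):
        with pytest.raises(InvalidInputError):
            ProductRecord(
                product_id="X",
                name="x",
                country="DE",
                wweia_code=5502,
                energy_per_100g=100,
                nutrients_per_100g={},
            )


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------


def brute_force_nrf(product: ProductRecord, standards: ReferenceStandards):
    """Independent recomputation straight from the two defining sums:
    NR = sum_i min(100 * content_i / DV_i * 100/ED, cap) and
    LIM = sum_i 100 * content_i / MRV_i * 100/ED."""
    ed = product.energy_per_100g
    nr = 0.0
    for nutrient, (dv, _) in standards.qualifying.items():
        content = product.nutrients_per_100g.get(nutrient) or 0.0
        nr += min(content / dv * 100.0 * 100.0 / ed, standards.cap)
    lim = 0.0
    for nutrient, (mrv, _) in standards.limiting.items():
        content = product.nutrients_per_100g.get(nutrient) or 0.0
        lim += content / mrv * 100.0 * 100.0 / ed
    return nr, lim, nr - lim


def test_oracle_equivalence_on_random_products(standards):
    """score_product agrees with the brute-force recomputation to 1e-9
    over 1,000 random products."""
    gen = np.random.default_rng(2061)
    for i in range(1000):
        product = random_product(gen, f"R{i}")
        result = score_product(product, standards)
        nr, lim, nrf = brute_force_nrf(product, standards)
        assert result.nr_subscore == pytest.approx(nr, abs=1e-9)
        assert result.lim_subscore == pytest.approx(lim, abs=1e-9)
        assert result.nrf_score == pytest.approx(nrf, abs=1e-9)


@given(seed=st.integers(0, 2**32 - 1))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_identity_and_bounds(seed, standards):
    """NRF == NR - LIM exactly; NR in [0, n*cap]; LIM >= 0; %DV <= cap."""
    product = random_product(np.random.default_rng(seed))
    result = score_product(product, standards)
    assert result.nrf_score == result.nr_subscore - result.lim_subscore
    assert 0 <= result.nr_subscore <= standards.n_qualifying * standards.cap
    assert result.lim_subscore >= 0
    assert all(0 <= v <= standards.cap for v in result.pct_dv_per_100kcal.values())


@given(
    seed=st.integers(0, 2**32 - 1),
    nutrient=st.sampled_from(list(ReferenceStandards().qualifying)),
    delta=st.floats(0.01, 50.0),
)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_monotone_in_qualifying_nutrients(seed, nutrient, delta, standards):
    """Adding a qualifying nutrient (energy fixed) never lowers NRF."""
    product = random_product(np.random.default_rng(seed))
    base = score_product(product, standards).nrf_score
    bumped = dict(product.nutrients_per_100g)
    bumped[nutrient] = bumped[nutrient] + delta
    product.nutrients_per_100g = bumped
    assert score_product(product, standards).nrf_score >= base - 1e-12


@given(
    seed=st.integers(0, 2**32 - 1),
    nutrient=st.sampled_from(["saturated_fat", "sodium"]),
    delta=st.floats(0.01, 50.0),
)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_antitone_in_limiting_nutrients(seed, nutrient, delta, standards):
    """Adding a limiting nutrient never raises NRF."""
    product = random_product(np.random.default_rng(seed))
    base = score_product(product, standards).nrf_score
    bumped = dict(product.nutrients_per_100g)
    bumped[nutrient] = bumped[nutrient] + delta
    product.nutrients_per_100g = bumped
    assert score_product(product, standards).nrf_score <= base + 1e-12


@given(seed=st.integers(0, 2**32 - 1), lam=st.floats(0.1, 10.0))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_scale_invariance(seed, lam, standards):
    """Scaling all per-100 g amounts and energy by the same factor leaves
    every per-100 kcal quantity and all three scores unchanged."""
    product = random_product(np.random.default_rng(seed))
    base = score_product(product, standards)
    scaled = ProductRecord(
        product_id=product.product_id,
        name=product.name,
        country=product.country,
        wweia_code=product.wweia_code,
        energy_per_100g=product.energy_per_100g * lam,
        nutrients_per_100g={
            k: v * lam for k, v in product.nutrients_per_100g.items()
        },
        total_sugar_per_100g=product.total_sugar_per_100g * lam,
        ingredient_text=product.ingredient_text,
    )
    result = score_product(scaled, standards)
    assert result.nr_subscore == pytest.approx(base.nr_subscore, rel=1e-9)
    assert result.lim_subscore == pytest.approx(base.lim_subscore, rel=1e-9)
    assert result.nrf_score == pytest.approx(base.nrf_score, rel=1e-9, abs=1e-9)
    assert result.total_sugar_pct_mrv == pytest.approx(
        base.total_sugar_pct_mrv, rel=1e-9
    )
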