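"""Seedable synthetic snack datasets with the statistical structure of a
261-product, 24-category children's-snack market survey.

The real multi-country snack sample behind the published summary tables is
proprietary, so this module generates stand-in datasets that preserve its
published structure: 24 WWEIA categories with fixed product counts and
energy-density targets, and two ingredient-defined contrasts whose group
nutrient profiles (as %DV / %MRV per 100 kcal) match the published group
means.

Generation model
----------------
* Energy density is drawn per category from a normal truncated below at
  the scorable minimum; the location is solved numerically so the
  *post-truncation* mean hits the category target.
* Each product receives intended ingredient flags (dairy-first,
  fruit-first, FVN) from per-category Bernoulli probabilities chosen so
  the expected group sizes match the survey (≈115 fruit-or-dairy-first
  vs ≈146 neither; ≈88 FVN vs ≈173 without).
* Nutrient contents are drawn per 100 kcal, conditioned jointly on the
  fruit-or-dairy-first and FVN flags, from zero-truncated normals.  The
  four cell means of that 2x2 classification are solved from the four
  published group margins: the two first-ingredient margins are
  preserved exactly (they are the primary calibration target) and the
  two FVN margins are met in least squares.  The per-product SD is
  SEM x sqrt(n) of the corresponding first-ingredient margin.  Amounts
  are then converted to per-100 g through the drawn energy density.
* Total sugar is drawn as added sugar plus an independent zero-truncated
  "naturally occurring" component, which enforces added <= total by
  construction while calibrating both published sugar rows in the mean.
* Ingredient labels are built from per-category templates whose term
  pools are chosen so the label's classification under the rule module
  equals the intended flags, exactly, for every product.

Everything is driven by one :class:`numpy.random.Generator`; identical
seed and config give byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .categories import CategoryMap, WweiaCategory
from .scoring import (
    DEFAULT_LIMITING,
    DEFAULT_QUALIFYING,
    DEFAULT_TOTAL_SUGAR_MRV,
    ED_MIN,
    ProductRecord,
)

#: Default seed shipped with the package so documentation examples are stable.
DEFAULT_SEED = 20200310 % (2**31)

QUALIFYING_NUTRIENTS = tuple(DEFAULT_QUALIFYING)
LIMITING_NUTRIENTS = tuple(DEFAULT_LIMITING)


# ---------------------------------------------------------------------------
# Calibrated truncated normals
# ---------------------------------------------------------------------------


def truncated_normal_location(target_mean: float, sd: float, lower: float) -> float:
    """Location mu such that a normal(mu, sd) truncated below at ``lower``
    has mean ``target_mean``.

    The truncated mean mu + sd*h((lower-mu)/sd), with h the normal hazard
    function, is strictly increasing in mu and spans (lower, inf), so the
    solution exists whenever ``target_mean > lower`` and is found by
    bracketing + brentq.
    """
    if sd <= 0:
        return target_mean
    if target_mean <= lower:
        raise ValueError(
            f"target mean {target_mean} must exceed the truncation bound {lower}"
        )

    def trunc_mean(mu: float) -> float:
        a = (lower - mu) / sd
        # hazard in log space: pdf/sf underflows for a >> 0
        hazard = np.exp(stats.norm.logpdf(a) - stats.norm.logsf(a))
        return mu + sd * hazard

    hi = target_mean  # trunc_mean(target) >= target always
    step = sd
    lo = target_mean - step
    for _ in range(80):  # geometric expansion: mu can sit many SDs below
        if trunc_mean(lo) < target_mean:
            break
        step *= 2.0
        lo -= step
    else:  # pragma: no cover - pathological parameters
        raise RuntimeError("failed to bracket truncated-normal location")
    from scipy.optimize import brentq

    return float(brentq(lambda mu: trunc_mean(mu) - target_mean, lo, hi, xtol=1e-10))


def draw_truncated_normal(
    rng: np.random.Generator,
    target_mean: float,
    sd: float,
    lower: float,
    size: int,
) -> np.ndarray:
    """Draw ``size`` values >= ``lower`` whose expectation is ``target_mean``."""
    if sd <= 0:
        return np.full(size, float(target_mean))
    mu = truncated_normal_location(target_mean, sd, lower)
    a = (lower - mu) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size,
                               random_state=rng)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


@dataclass
class GroupProfile:
    """Per-100 kcal nutrient targets for one generator cell (a joint
    first-ingredient x FVN stratum).

    ``pct_dv`` maps qualifying nutrient -> (mean %DV, per-product SD);
    ``pct_mrv`` maps saturated_fat / added_sugar / sodium -> (mean %MRV,
    SD); ``natural_sugar`` is the zero-truncated component added to added
    sugar so that total sugar matches its published row in the mean.
    """

    pct_dv: dict[str, tuple[float, float]]
    pct_mrv: dict[str, tuple[float, float]]
    natural_sugar: tuple[float, float]  # (mean %MRV-equivalent, SD)


@dataclass
class CategoryGeneratorSpec:
    """Recipe for one WWEIA category's synthetic products."""

    category: WweiaCategory
    n: int
    ed_mean: float
    ed_sd: float
    p_dairy_first: float
    p_fruit_first: float
    water_lead: bool
    p_fvn_extra: float  # P(FVN ingredient present | not fruit-first)
    kind: str  # label-template family

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.ed_sd < 0:
            raise ValueError("ed_sd must be >= 0")
        if self.ed_mean <= ED_MIN:
            raise ValueError(f"ed_mean must exceed ED_MIN={ED_MIN}")


@dataclass
class DatasetConfig:
    specs: list[CategoryGeneratorSpec]
    group_profiles: dict[str, GroupProfile]  # keyed by CELL_KEYS
    seed: int = DEFAULT_SEED
    country_weights: dict[str, float] = field(
        default_factory=lambda: {"US": 0.25, "CA": 0.25, "FR": 0.25, "UK": 0.25}
    )
    added_sugar_floor: float = 0.0

    @property
    def total_n(self) -> int:
        return sum(s.n for s in self.specs)

    # -- YAML round trip --------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "country_weights": self.country_weights,
            "group_profiles": {
                key: {
                    "pct_dv": {
                        k: [float(x) for x in v] for k, v in gp.pct_dv.items()
                    },
                    "pct_mrv": {
                        k: [float(x) for x in v] for k, v in gp.pct_mrv.items()
                    },
                    "natural_sugar": [float(x) for x in gp.natural_sugar],
                }
                for key, gp in self.group_profiles.items()
            },
            "specs": [
                {
                    "row_index": s.category.row_index,
                    "label": s.category.label,
                    "codes": sorted(s.category.codes),
                    "n": s.n,
                    "ed_mean": s.ed_mean,
                    "ed_sd": s.ed_sd,
                    "p_dairy_first": s.p_dairy_first,
                    "p_fruit_first": s.p_fruit_first,
                    "water_lead": s.water_lead,
                    "p_fvn_extra": s.p_fvn_extra,
                    "kind": s.kind,
                }
                for s in self.specs
            ],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetConfig":
        raw = yaml.safe_load(Path(path).read_text())
        profiles = {
            key: GroupProfile(
                pct_dv={k: tuple(v) for k, v in gp["pct_dv"].items()},
                pct_mrv={k: tuple(v) for k, v in gp["pct_mrv"].items()},
                natural_sugar=tuple(gp["natural_sugar"]),
            )
            for key, gp in raw["group_profiles"].items()
        }
        specs = [
            CategoryGeneratorSpec(
                category=WweiaCategory(
                    row_index=int(s["row_index"]),
                    label=str(s["label"]),
                    codes=frozenset(int(c) for c in s["codes"]),
                ),
                n=int(s["n"]),
                ed_mean=float(s["ed_mean"]),
                ed_sd=float(s["ed_sd"]),
                p_dairy_first=float(s["p_dairy_first"]),
                p_fruit_first=float(s["p_fruit_first"]),
                water_lead=bool(s["water_lead"]),
                p_fvn_extra=float(s["p_fvn_extra"]),
                kind=str(s["kind"]),
            )
            for s in raw["specs"]
        ]
        return cls(
            specs=specs,
            group_profiles=profiles,
            seed=int(raw["seed"]),
            country_weights={k: float(v) for k, v in raw["country_weights"].items()},
        )


def load_reference_group_summary() -> pd.DataFrame:
    """The published benchmark group statistics (both contrasts), as
    shipped with the package."""
    path = resources.files("snacknrf.data").joinpath("reference_group_summary.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def load_category_calibration() -> pd.DataFrame:
    """Per-category calibration targets (n, energy density, LIM/NRF
    summary targets) and template parameters."""
    path = resources.files("snacknrf.data").joinpath("category_calibration.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


#: Generator cell keys for the 2x2 (first-ingredient x FVN) classification.
CELL_KEYS = ("flagged_fvn", "flagged_nofvn", "neither_fvn", "neither_nofvn")

#: Smallest admissible cell mean on the percent scale (the zero-truncated
#: draw needs a strictly positive target).
_CELL_FLOOR = 0.05

_PROFILE_VARIABLES = tuple(f"pct_dv_{n}" for n in QUALIFYING_NUTRIENTS) + (
    "pct_mrv_saturated_fat",
    "pct_mrv_added_sugar",
    "pct_mrv_sodium",
    "pct_mrv_total_sugar",
)


def expected_cell_weights(specs: list["CategoryGeneratorSpec"]) -> dict[str, float]:
    """Expected product counts of the four (first-ingredient x FVN) cells
    under the config's Bernoulli flag probabilities."""
    w = dict.fromkeys(CELL_KEYS, 0.0)
    for s in specs:
        p_extra = 1.0 if s.kind == "nuts" else s.p_fvn_extra
        e_flagged_fvn = s.p_dairy_first * p_extra + (1 - s.p_dairy_first) * s.p_fruit_first
        e_flagged = s.p_dairy_first + (1 - s.p_dairy_first) * s.p_fruit_first
        e_neither_fvn = (1 - s.p_dairy_first) * (1 - s.p_fruit_first) * p_extra
        w["flagged_fvn"] += s.n * e_flagged_fvn
        w["flagged_nofvn"] += s.n * (e_flagged - e_flagged_fvn)
        w["neither_fvn"] += s.n * e_neither_fvn
        w["neither_nofvn"] += s.n * ((1 - e_flagged) - e_neither_fvn)
    return w


def _solve_cell_means(
    ref: pd.DataFrame, weights: dict[str, float]
) -> dict[str, dict[str, float]]:
    """Per-variable cell means of the 2x2 classification.

    The two first-ingredient margins are reproduced exactly by
    construction (a mean-preserving tilt within each margin); the tilt
    parameters are then chosen by least squares against the two FVN
    margins, which cannot both be exact because the four published
    margins over-determine the table.  Cells driven below the floor are
    clamped and their margin partner re-balanced, keeping the
    first-ingredient margins exact.
    """
    wFV, wFO = weights["flagged_fvn"], weights["flagged_nofvn"]
    wNV, wNO = weights["neither_fvn"], weights["neither_nofvn"]
    wF, wN = wFV + wFO, wNV + wNO
    wV, wO = wFV + wNV, wFO + wNO

    def margin(contrast: str, group: str, var: str) -> float:
        sub = ref[
            (ref.contrast == contrast) & (ref.group == group) & (ref.variable == var)
        ]
        return float(sub["mean"].iloc[0])

    cells: dict[str, dict[str, float]] = {key: {} for key in CELL_KEYS}
    for var in _PROFILE_VARIABLES:
        m_f = margin("first_ingredient", "fruit_or_dairy", var)
        m_n = margin("first_ingredient", "neither", var)
        m_v = margin("fvn", "fvn", var)
        m_o = margin("fvn", "no_fvn", var)
        # x_FV = m_f + a*wFO/wF, x_FO = m_f - a*wFV/wF (flagged margin exact);
        # likewise b tilts the neither margin.  Fit (a, b) to the FVN margins.
        design = np.array(
            [[wFV * wFO / wF, wNV * wNO / wN], [-wFO * wFV / wF, -wNO * wNV / wN]]
        )
        rhs = np.array(
            [wV * m_v - (wFV * m_f + wNV * m_n), wO * m_o - (wFO * m_f + wNO * m_n)]
        )
        (a, b), *_ = np.linalg.lstsq(design, rhs, rcond=None)
        x = {
            "flagged_fvn": m_f + a * wFO / wF,
            "flagged_nofvn": m_f - a * wFV / wF,
            "neither_fvn": m_n + b * wNO / wN,
            "neither_nofvn": m_n - b * wNV / wN,
        }
        for key, partner, w_key, w_partner, m_target in (
            ("flagged_fvn", "flagged_nofvn", wFV, wFO, m_f),
            ("flagged_nofvn", "flagged_fvn", wFO, wFV, m_f),
            ("neither_fvn", "neither_nofvn", wNV, wNO, m_n),
            ("neither_nofvn", "neither_fvn", wNO, wNV, m_n),
        ):
            if x[key] < _CELL_FLOOR:
                x[key] = _CELL_FLOOR
                x[partner] = ((w_key + w_partner) * m_target - w_key * _CELL_FLOOR) / w_partner
        for key in CELL_KEYS:
            cells[key][var] = float(x[key])
    return cells


def _profiles_from_reference(
    ref: pd.DataFrame, specs: list["CategoryGeneratorSpec"]
) -> dict[str, GroupProfile]:
    """Build the four cell profiles from the published margins."""
    weights = expected_cell_weights(specs)
    cells = _solve_cell_means(ref, weights)

    def margin_sd(group: str, var: str) -> float:
        sub = ref[
            (ref.contrast == "first_ingredient")
            & (ref.group == group)
            & (ref.variable == var)
        ]
        return float(sub["sem"].iloc[0] * np.sqrt(sub["n"].iloc[0]))

    profiles: dict[str, GroupProfile] = {}
    for key in CELL_KEYS:
        group = "fruit_or_dairy" if key.startswith("flagged") else "neither"
        means = cells[key]
        pct_dv = {
            nut: (means[f"pct_dv_{nut}"], margin_sd(group, f"pct_dv_{nut}"))
            for nut in QUALIFYING_NUTRIENTS
        }
        pct_mrv = {
            nut: (
                means[f"pct_mrv_{nut}"],
                margin_sd(group, f"pct_mrv_{nut}"),
            )
            for nut in ("saturated_fat", "added_sugar", "sodium")
        }
        # naturally occurring sugar tops added sugar up to the total-sugar
        # target; its spread is set to its mean (CV = 1).  The floor keeps
        # the added <= total invariant satisfiable even where the published
        # margins put added sugar above total sugar.
        nat_mean = max(
            means["pct_mrv_total_sugar"] - means["pct_mrv_added_sugar"], 0.5
        )
        profiles[key] = GroupProfile(
            pct_dv=pct_dv, pct_mrv=pct_mrv, natural_sugar=(nat_mean, nat_mean)
        )
    return profiles


def default_config(seed: int = DEFAULT_SEED) -> DatasetConfig:
    """The shipped study-scale configuration: 261 products in 24 WWEIA
    categories with published energy-density targets, and group nutrient
    profiles calibrated to the published first-ingredient contrast."""
    cmap = CategoryMap.default()
    calib = load_category_calibration()
    ref = load_reference_group_summary()
    by_row = {c.row_index: c for c in cmap}
    specs = [
        CategoryGeneratorSpec(
            category=by_row[int(row.row_index)],
            n=int(row.n),
            ed_mean=float(row.ed_mean),
            ed_sd=float(row.ed_sd),
            p_dairy_first=float(row.p_dairy_first),
            p_fruit_first=float(row.p_fruit_first),
            water_lead=bool(row.water_lead),
            p_fvn_extra=float(row.p_fvn_extra),
            kind=str(row.kind),
        )
        for row in calib.itertuples()
    ]
    profiles = _profiles_from_reference(ref, specs)
    return DatasetConfig(specs=specs, group_profiles=profiles, seed=seed)


def scale_config(config: DatasetConfig, factor: int) -> DatasetConfig:
    """Multiply every category's product count by ``factor`` (for
    large-sample calibration checks)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    specs = [
        CategoryGeneratorSpec(
            category=s.category,
            n=s.n * factor,
            ed_mean=s.ed_mean,
            ed_sd=s.ed_sd,
            p_dairy_first=s.p_dairy_first,
            p_fruit_first=s.p_fruit_first,
            water_lead=s.water_lead,
            p_fvn_extra=s.p_fvn_extra,
            kind=s.kind,
        )
        for s in config.specs
    ]
    return DatasetConfig(
        specs=specs,
        group_profiles=config.group_profiles,
        seed=config.seed,
        country_weights=dict(config.country_weights),
    )


# ---------------------------------------------------------------------------
# Ingredient-label templates
# ---------------------------------------------------------------------------

_FRUIT_FIRST_POOL = (
    "apple",
    "apples",
    "strawberries",
    "banana puree",
    "apple puree",
    "grapes",
    "mango",
    "peaches",
)
_DRIED_FRUIT_POOL = ("raisins", "dried apricots", "dried cranberries", "prunes")
_JUICE_FRUIT_POOL = ("oranges", "apples", "grapes", "pineapple")
_DAIRY_MILK_POOL = ("low fat milk", "skim milk", "whole milk", "milk")
_DAIRY_YOGURT_POOL = ("yogurt", "greek yogurt", "low fat yogurt", "whole milk yogurt")
_DAIRY_CHEESE_POOL = ("cheddar cheese", "mozzarella cheese", "cheese", "swiss cheese")
_NUT_POOL = ("almonds", "peanuts", "cashews", "sunflower seeds", "walnuts")
_YOGURT_FRUIT_POOL = ("strawberries", "blueberries", "raspberries", "peaches")
_SAFE_FILLERS = (
    "sugar",
    "cane sugar",
    "glucose syrup",
    "tapioca syrup",
    "wheat flour",
    "rice flour",
    "palm oil",
    "canola oil",
    "salt",
    "natural flavor",
    "cocoa",
    "soy lecithin",
    "baking soda",
    "citric acid",
    "gelatin",
    "cornstarch",
    "carrageenan",
    "guar gum",
)


def _fillers(rng: np.random.Generator, k: int) -> list[str]:
    return list(rng.choice(_SAFE_FILLERS, size=k, replace=False))


def generate_ingredient_label(
    spec: CategoryGeneratorSpec,
    rng: np.random.Generator,
    dairy_first: bool,
    fruit_first: bool,
    fvn: bool,
) -> str:
    """Build a label whose classification equals the intended flags.

    Templates imitate real back-of-pack phrasing per category family
    (cream-first ice creams, water-leading juices, concentrate-sweetened
    fruit drinks) while drawing only from pools that the rule lexicons
    resolve the intended way.
    """
    kind = spec.kind
    if dairy_first:
        if kind == "cheese":
            first = rng.choice(_DAIRY_CHEESE_POOL)
            rest = ["salt", "enzymes", "annatto color"]
        elif kind == "yogurt":
            first = rng.choice(_DAIRY_YOGURT_POOL)
            rest = ["sugar", "corn starch", "natural flavor"]
            if fvn:
                fruit = rng.choice(_YOGURT_FRUIT_POOL)
                quid = rng.integers(5, 15)
                rest.insert(1, f"{fruit} ({quid}%)")
        else:  # milk, pudding
            first = rng.choice(_DAIRY_MILK_POOL)
            rest = ["sugar", "cocoa", "carrageenan", "vitamin d3"]
        if rng.random() < 0.3:
            first = f"{first} ({rng.integers(50, 95)}%)"
        return ", ".join([str(first)] + rest)

    if fruit_first:
        if spec.water_lead:
            fruit = rng.choice(_JUICE_FRUIT_POOL)
            return ", ".join(["water", str(fruit), "ascorbic acid"])
        pool = _DRIED_FRUIT_POOL if kind == "dried_fruit" else _FRUIT_FIRST_POOL
        first = rng.choice(pool)
        if kind == "candy_fruit":
            rest = ["sugar", "glucose syrup", "pectin", "citric acid"]
        else:
            rest = ["lemon juice concentrate", "ascorbic acid"]
        return ", ".join([str(first)] + rest)

    # neither-first templates
    if kind == "ice_cream":
        rest = ["cream", "skim milk", "sugar", "egg yolks", "natural flavor"]
    elif kind == "chips_potato":
        rest = ["potatoes", "vegetable oil", "salt"]
    elif kind == "chips_corn":
        rest = ["corn", "vegetable oil", "salt"]
    elif kind == "soda":
        rest = ["carbonated water", "sugar", "caramel color", "phosphoric acid",
                "natural flavor"]
    elif kind == "fruit_drink":
        rest = ["water", "sugar", "orange juice concentrate", "citric acid"]
    elif kind == "ices":
        rest = ["water", "sugar", "glucose syrup", "citric acid", "natural flavor"]
    elif kind == "candy_fruit":
        rest = ["sugar", "glucose syrup", "apple juice concentrate", "pectin",
                "natural flavor"]
    elif kind == "candy_choc":
        rest = ["sugar", "cocoa butter", "chocolate", "skim milk powder",
                "soy lecithin"]
    elif kind == "bar":
        rest = ["oats", "tapioca syrup", "honey"] + _fillers(rng, 2)
    elif kind == "nuts":
        rest = []  # nuts kind is always FVN; handled below
    else:  # bakery, cake, crackers, popcorn, pudding without dairy
        rest = ["wheat flour", "sugar"] + _fillers(rng, 3)

    if fvn:
        if kind == "nuts":
            first = rng.choice(_NUT_POOL)
            rest = [str(first), "sea salt", "canola oil"]
        else:
            insert_at = max(1, min(2, len(rest)))
            rest = list(rest)
            rest.insert(insert_at, str(rng.choice(_NUT_POOL)))
    elif kind == "nuts":  # pragma: no cover - nuts specs always draw FVN
        rest = ["oats", "tapioca syrup", "sea salt"]
    return ", ".join(rest)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

_COUNTRY_ORDER = ("US", "CA", "FR", "UK")


def _draw_group_nutrients(
    rng: np.random.Generator, profile: GroupProfile, size: int
) -> dict[str, np.ndarray]:
    """Per-100 kcal nutrient amounts (DV/MRV units) for ``size`` products."""
    out: dict[str, np.ndarray] = {}
    for nutrient, (mean_pct, sd_pct) in profile.pct_dv.items():
        dv = DEFAULT_QUALIFYING[nutrient][0]
        pct = draw_truncated_normal(rng, mean_pct, sd_pct, 0.0, size)
        out[nutrient] = pct / 100.0 * dv
    for nutrient, (mean_pct, sd_pct) in profile.pct_mrv.items():
        mrv = DEFAULT_LIMITING[nutrient][0]
        pct = draw_truncated_normal(rng, mean_pct, sd_pct, 0.0, size)
        out[nutrient] = pct / 100.0 * mrv
    nat_mean, nat_sd = profile.natural_sugar
    nat_pct = draw_truncated_normal(rng, nat_mean, nat_sd, 0.0, size)
    out["natural_sugar"] = nat_pct / 100.0 * DEFAULT_TOTAL_SUGAR_MRV
    return out


def generate_dataset_with_flags(
    config: DatasetConfig,
) -> tuple[list[ProductRecord], pd.DataFrame]:
    """Generate products plus a parallel frame of the intended flags.

    The flags frame has columns ``product_id, dairy_first, fruit_first,
    fruit_or_dairy_first, fvn`` and is what the label templates promised;
    the rule module must recover it exactly.
    """
    rng = np.random.default_rng(config.seed)
    countries = list(config.country_weights)
    weights = np.array([config.country_weights[c] for c in countries], dtype=float)
    weights = weights / weights.sum()

    records: list[ProductRecord] = []
    flag_rows: list[dict] = []
    counter = 0
    for spec in config.specs:
        n = spec.n
        dairy = rng.random(n) < spec.p_dairy_first
        fruit = (~dairy) & (rng.random(n) < spec.p_fruit_first)
        fvn = fruit | (rng.random(n) < spec.p_fvn_extra)
        if spec.kind == "nuts":
            fvn[:] = True
        flagged = dairy | fruit

        ed = draw_truncated_normal(rng, spec.ed_mean, spec.ed_sd, ED_MIN, n)
        # nutrient draws conditioned jointly on (first-ingredient, FVN)
        amounts = {}
        cell_masks = (
            ("flagged_fvn", flagged & fvn),
            ("flagged_nofvn", flagged & ~fvn),
            ("neither_fvn", ~flagged & fvn),
            ("neither_nofvn", ~flagged & ~fvn),
        )
        for key, mask in cell_masks:
            k = int(mask.sum())
            if k:
                amounts[key] = (mask, _draw_group_nutrients(
                    rng, config.group_profiles[key], k))

        per_product: dict[str, np.ndarray] = {}
        names = list(QUALIFYING_NUTRIENTS) + list(LIMITING_NUTRIENTS) + [
            "natural_sugar"
        ]
        for name in names:
            col = np.empty(n)
            for key, (mask, drawn) in amounts.items():
                col[mask] = drawn[name]
            per_product[name] = col

        country_idx = rng.choice(len(countries), size=n, p=weights)
        for i in range(n):
            counter += 1
            pid = f"P{counter:04d}"
            ed_i = float(ed[i])
            nutrients: dict[str, float] = {}
            for nutrient in QUALIFYING_NUTRIENTS + LIMITING_NUTRIENTS:
                nutrients[nutrient] = float(per_product[nutrient][i] * ed_i / 100.0)
            total_sugar = float(
                (per_product["added_sugar"][i] + per_product["natural_sugar"][i])
                * ed_i
                / 100.0
            )
            label = generate_ingredient_label(
                spec, rng, bool(dairy[i]), bool(fruit[i]), bool(fvn[i])
            )
            records.append(
                ProductRecord(
                    product_id=pid,
                    name=f"{spec.kind.replace('_', ' ')} snack {counter}",
                    country=countries[int(country_idx[i])],
                    wweia_code=min(spec.category.codes),
                    energy_per_100g=ed_i,
                    nutrients_per_100g=nutrients,
                    total_sugar_per_100g=total_sugar,
                    ingredient_text=label,
                )
            )
            flag_rows.append(
                {
                    "product_id": pid,
                    "dairy_first": bool(dairy[i]),
                    "fruit_first": bool(fruit[i]),
                    "fruit_or_dairy_first": bool(dairy[i] or fruit[i]),
                    "fvn": bool(fvn[i]),
                }
            )
    return records, pd.DataFrame(flag_rows)


def generate_dataset(config: DatasetConfig) -> list[ProductRecord]:
    """Generate the configured synthetic snack dataset (records only)."""
    records, _ = generate_dataset_with_flags(config)
    return records
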