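"""Nutrient-density scoring: energy density, per-100-kcal normalization,
percent daily values, and the NRFn.3 family of scores.

The Nutrient Rich Food index NRFn.3 summarizes a food's nutrient density as

    NRFn.3 = NRn - LIM

where NRn is the sum over *n* qualifying nutrients of percent daily value
(%DV) per 100 kcal, each truncated at 100, and LIM is the sum over the three
nutrients to limit (saturated fat, added sugar, sodium) of percent maximum
recommended value (%MRV) per 100 kcal, untruncated.  The shipped default is
NRF8.3 with eight qualifying nutrients: protein, fiber, vitamins A, C and D,
calcium, iron, and potassium.  A %MRV for total sugar is computed and
reported alongside but never enters LIM, because total sugars include those
naturally present in fruit and dairy.

All scores are computed on a 100-kcal basis.  Products whose energy density
falls below :data:`ED_MIN` cannot be normalized to 100 kcal and raise
:class:`~snacknrf.errors.UnscorableProductError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import (
    ConfigurationError,
    InvalidInputError,
    UnscorableProductError,
)

logger = logging.getLogger(__name__)

#: Minimum scorable energy density (kcal/100 g).  The 100-kcal basis is
#: undefined for (near-)zero-energy foods; real snack categories all sit
#: at 40 kcal/100 g or above, so 1 kcal/100 g only excludes degenerate
#: records such as plain water.
ED_MIN: float = 1.0

#: Default %DV truncation ceiling for qualifying nutrients.
DEFAULT_CAP: float = 100.0

# US-based daily values (DV) for the eight default qualifying nutrients,
# and maximum recommended values (MRV) for the three nutrients to limit.
# A single US set is applied to all markets for cross-country uniformity.
DEFAULT_QUALIFYING: dict[str, tuple[float, str]] = {
    "protein": (50.0, "g"),
    "fiber": (28.0, "g"),
    "vitamin_a": (800.0, "ug"),
    "vitamin_c": (80.0, "mg"),
    "vitamin_d": (15.0, "ug"),
    "calcium": (1000.0, "mg"),
    "iron": (18.0, "mg"),
    "potassium": (4700.0, "mg"),
}

DEFAULT_LIMITING: dict[str, tuple[float, str]] = {
    "added_sugar": (50.0, "g"),
    "saturated_fat": (20.0, "g"),
    "sodium": (2400.0, "mg"),
}

DEFAULT_TOTAL_SUGAR_MRV: float = 50.0  # g; same reference as added sugar


@dataclass(frozen=True)
class ReferenceStandards:
    """Reference amounts defining one NRFn.3 variant.

    Parameters
    ----------
    qualifying
        Ordered map nutrient name -> (daily value, unit).  The size of this
        map is the *n* in NRFn.3; it may range from 1 to 15 nutrients.
    limiting
        Ordered map nutrient name -> (maximum recommended value, unit).
    total_sugar_mrv
        Reference amount (g) for the separately reported total-sugar %MRV.
    cap
        Truncation ceiling applied to qualifying %DVs only.
    """

    qualifying: dict[str, tuple[float, str]] = field(
        default_factory=lambda: dict(DEFAULT_QUALIFYING)
    )
    limiting: dict[str, tuple[float, str]] = field(
        default_factory=lambda: dict(DEFAULT_LIMITING)
    )
    total_sugar_mrv: float = DEFAULT_TOTAL_SUGAR_MRV
    cap: float = DEFAULT_CAP

    def __post_init__(self):
        if not 1 <= len(self.qualifying) <= 15:
            raise ConfigurationError(
                f"qualifying set size must be in [1, 15], got {len(self.qualifying)}"
            )
        if not self.limiting:
            raise ConfigurationError("limiting set must be non-empty")
        for name, (value, _unit) in {**self.qualifying, **self.limiting}.items():
            if not value > 0:
                raise ConfigurationError(
                    f"reference amount for {name!r} must be strictly positive"
                )
        if not self.total_sugar_mrv > 0:
            raise ConfigurationError("total_sugar_mrv must be strictly positive")
        if not self.cap > 0:
            raise ConfigurationError("cap must be strictly positive")

    @property
    def n_qualifying(self) -> int:
        return len(self.qualifying)

    def dv(self, nutrient: str) -> float:
        try:
            return self.qualifying[nutrient][0]
        except KeyError:
            raise ConfigurationError(
                f"{nutrient!r} is not a qualifying nutrient of this standard"
            ) from None

    def mrv(self, nutrient: str) -> float:
        if nutrient == "total_sugar":
            return self.total_sugar_mrv
        try:
            return self.limiting[nutrient][0]
        except KeyError:
            raise ConfigurationError(
                f"{nutrient!r} is not a limiting nutrient of this standard"
            ) from None

    # -- config-file round trip ------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceStandards":
        """Load a standard from a key-value config file.

        Layout::

            qualifying:
              protein: {amount: 50, unit: g}
              ...
            limiting:
              added_sugar: {amount: 50, unit: g}
              ...
            total_sugar_mrv: 50
            cap: 100
        """
        raw = yaml.safe_load(Path(path).read_text())
        try:
            qualifying = {
                k: (float(v["amount"]), str(v["unit"]))
                for k, v in raw["qualifying"].items()
            }
            limiting = {
                k: (float(v["amount"]), str(v["unit"]))
                for k, v in raw["limiting"].items()
            }
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed standards file {path}: {exc}") from exc
        return cls(
            qualifying=qualifying,
            limiting=limiting,
            total_sugar_mrv=float(raw.get("total_sugar_mrv", DEFAULT_TOTAL_SUGAR_MRV)),
            cap=float(raw.get("cap", DEFAULT_CAP)),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "qualifying": {
                k: {"amount": v, "unit": u} for k, (v, u) in self.qualifying.items()
            },
            "limiting": {
                k: {"amount": v, "unit": u} for k, (v, u) in self.limiting.items()
            },
            "total_sugar_mrv": self.total_sugar_mrv,
            "cap": self.cap,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class ProductRecord:
    """One snack's per-100 g composition and label metadata.

    ``nutrients_per_100g`` uses the same nutrient names and units as the
    reference standard it will be scored against.  ``total_sugar_per_100g``
    is kept separate from the limiting added-sugar entry because it feeds
    the separately reported total-sugar %MRV only.
    """

    product_id: str
    name: str
    country: str
    wweia_code: int
    energy_per_100g: float
    nutrients_per_100g: dict[str, float]
    total_sugar_per_100g: float | None = None
    ingredient_text: str = ""
    serving_size_g: float | None = None

    VALID_COUNTRIES = frozenset({"US", "CA", "FR", "UK"})

    def __post_init__(self):
        if self.country not in self.VALID_COUNTRIES:
            raise InvalidInputError(
                f"country must be one of {sorted(self.VALID_COUNTRIES)}, "
                f"got {self.country!r}"
            )
        if self.energy_per_100g < 0:
            raise InvalidInputError("energy_per_100g must be >= 0")
        for nutrient, amount in self.nutrients_per_100g.items():
            if amount is not None and amount < 0:
                raise InvalidInputError(
                    f"nutrient amount for {nutrient!r} must be >= 0, got {amount}"
                )
        if self.total_sugar_per_100g is not None and self.total_sugar_per_100g < 0:
            raise InvalidInputError("total_sugar_per_100g must be >= 0")
        added = self.nutrients_per_100g.get("added_sugar")
        if (
            added is not None
            and self.total_sugar_per_100g is not None
            and added > self.total_sugar_per_100g + 1e-9
        ):
            raise InvalidInputError(
                f"added sugar ({added} g) exceeds total sugar "
                f"({self.total_sugar_per_100g} g) for product {self.product_id!r}"
            )


@dataclass
class ScoreResult:
    """Per-product scoring output on the 100-kcal basis."""

    product_id: str
    energy_density: float
    pct_dv_per_100kcal: dict[str, float]
    pct_dv_uncapped: dict[str, float]
    pct_mrv_per_100kcal: dict[str, float]
    total_sugar_pct_mrv: float | None
    nr_subscore: float
    lim_subscore: float
    nrf_score: float


def energy_density(energy_kcal: float, mass_g: float) -> float:
    """Energy density in kcal/100 g for ``energy_kcal`` in ``mass_g`` of food."""
    if mass_g <= 0:
        raise InvalidInputError(f"mass_g must be > 0, got {mass_g}")
    if energy_kcal < 0:
        raise InvalidInputError(f"energy_kcal must be >= 0, got {energy_kcal}")
    return energy_kcal * 100.0 / mass_g


def amount_per_100kcal(
    amount_per_100g: float, ed: float, product_id: str = "<unknown>"
) -> float:
    """Convert a per-100 g amount to the 100-kcal basis given energy density."""
    if ed < ED_MIN:
        raise UnscorableProductError(product_id, ed)
    return amount_per_100g * 100.0 / ed


def percent_dv(
    nutrient: str,
    amount_per_100kcal: float,
    standards: ReferenceStandards,
) -> tuple[float, float]:
    """(capped, uncapped) %DV per 100 kcal for a qualifying nutrient."""
    dv = standards.dv(nutrient)
    uncapped = amount_per_100kcal / dv * 100.0
    return min(uncapped, standards.cap), uncapped


def percent_mrv(
    nutrient: str,
    amount_per_100kcal: float,
    standards: ReferenceStandards,
) -> float:
    """%MRV per 100 kcal for a limiting nutrient (or ``"total_sugar"``).

    Limiting nutrients are deliberately not capped: truncation applies only
    to nutrients to encourage, so all-sugar candy can exceed 100 %MRV.
    """
    return amount_per_100kcal / standards.mrv(nutrient) * 100.0


def score_product(
    product: ProductRecord,
    standards: ReferenceStandards | None = None,
) -> ScoreResult:
    """Score one product: capped %DVs, %MRVs, NR, LIM, and NRF = NR - LIM.

    Missing nutrient values contribute 0 to the sub-scores and are logged
    as warnings; a product with energy density below :data:`ED_MIN` raises
    :class:`~snacknrf.errors.UnscorableProductError`.
    """
    if standards is None:
        standards = ReferenceStandards()
    ed = product.energy_per_100g  # per-100 g records: ED is the energy field
    if ed < ED_MIN:
        raise UnscorableProductError(product.product_id, ed)

    pct_dv_capped: dict[str, float] = {}
    pct_dv_raw: dict[str, float] = {}
    for nutrient in standards.qualifying:
        amount = product.nutrients_per_100g.get(nutrient)
        if amount is None:
            logger.warning(
                "product %s: missing qualifying nutrient %r; contributes 0 to NR",
                product.product_id,
                nutrient,
            )
            pct_dv_capped[nutrient] = 0.0
            pct_dv_raw[nutrient] = 0.0
            continue
        per_100kcal = amount_per_100kcal(amount, ed, product.product_id)
        capped, uncapped = percent_dv(nutrient, per_100kcal, standards)
        pct_dv_capped[nutrient] = capped
        pct_dv_raw[nutrient] = uncapped

    pct_mrv: dict[str, float] = {}
    for nutrient in standards.limiting:
        amount = product.nutrients_per_100g.get(nutrient)
        if amount is None:
            logger.warning(
                "product %s: missing limiting nutrient %r; contributes 0 to LIM",
                product.product_id,
                nutrient,
            )
            pct_mrv[nutrient] = 0.0
            continue
        per_100kcal = amount_per_100kcal(amount, ed, product.product_id)
        pct_mrv[nutrient] = percent_mrv(nutrient, per_100kcal, standards)

    total_sugar_pct: float | None = None
    if product.total_sugar_per_100g is not None:
        total_sugar_pct = percent_mrv(
            "total_sugar",
            amount_per_100kcal(product.total_sugar_per_100g, ed, product.product_id),
            standards,
        )

    nr = sum(pct_dv_capped.values())
    lim = sum(pct_mrv.values())
    return ScoreResult(
        product_id=product.product_id,
        energy_density=ed,
        pct_dv_per_100kcal=pct_dv_capped,
        pct_dv_uncapped=pct_dv_raw,
        pct_mrv_per_100kcal=pct_mrv,
        total_sugar_pct_mrv=total_sugar_pct,
        nr_subscore=nr,
        lim_subscore=lim,
        nrf_score=nr - lim,
    )
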