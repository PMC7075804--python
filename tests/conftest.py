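import numpy as np
import pytest

from snacknrf import (
    ReferenceStandards,
    default_config,
    generate_dataset_with_flags,
)
from snacknrf.pipeline import run_pipeline


@pytest.fixture(scope="session")
def standards() -> ReferenceStandards:
    return ReferenceStandards()


@pytest.fixture(scope="session")
def default_dataset():
    """The shipped 261-product synthetic dataset with intended flags."""
    config = default_config()
    records, flags = generate_dataset_with_flags(config)
    return config, records, flags


@pytest.fixture(scope="session")
def default_pipeline_result(default_dataset):
    _, records, _ = default_dataset
    return run_pipeline(records)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_product(rng: np.random.Generator, product_id: str = "R1"):
    """A random but valid product for property tests."""
    from snacknrf import ProductRecord

    ed = float(rng.uniform(20, 600))
    nutrients = {
        "protein": float(rng.uniform(0, 20)),
        "fiber": float(rng.uniform(0, 10)),
        "vitamin_a": float(rng.uniform(0, 1000)),
        "vitamin_c": float(rng.uniform(0, 150)),
        "vitamin_d": float(rng.uniform(0, 20)),
        "calcium": float(rng.uniform(0, 1200)),
        "iron": float(rng.uniform(0, 20)),
        "potassium": float(rng.uniform(0, 2000)),
        "saturated_fat": float(rng.uniform(0, 30)),
        "added_sugar": float(rng.uniform(0, 40)),
        "sodium": float(rng.uniform(0, 1500)),
    }
    total_sugar = nutrients["added_sugar"] + float(rng.uniform(0, 20))
    return ProductRecord(
        product_id=product_id,
        name="random snack",
        country="US",
        wweia_code=5502,
        energy_per_100g=ed,
        nutrients_per_100g=nutrients,
        total_sugar_per_100g=total_sugar,
        ingredient_text="sugar, wheat flour, palm oil",
    )
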