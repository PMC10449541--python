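import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from felkit import FoodRecord, FoodTable, default_group_profiles, generate_food_table

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def plain_record():
    """A fully specified, internally consistent solid food."""
    return FoodRecord(
        name="oatmeal",
        group="Cereal with low-fat content",
        state="solid",
        energy=370.0,
        protein=13.0,
        total_lipids=7.0,
        saturated_fat=1.2,
        cholesterol=0.0,
        carbohydrates=68.0,
        sugar=1.0,
        fiber=10.0,
        sodium=5.0,
    )


@pytest.fixture
def small_table():
    """Four hand-made foods spanning two groups."""
    recs = [
        FoodRecord(name="apple", group="Fruits", energy=52, protein=0.3,
                   total_lipids=0.2, saturated_fat=0.0, cholesterol=0,
                   carbohydrates=14, sugar=10, fiber=2.4, sodium=1),
        FoodRecord(name="banana", group="Fruits", energy=89, protein=1.1,
                   total_lipids=0.3, saturated_fat=0.1, cholesterol=0,
                   carbohydrates=23, sugar=12, fiber=2.6, sodium=1),
        FoodRecord(name="chicken", group="Meats", energy=165, protein=31,
                   total_lipids=3.6, saturated_fat=1.0, cholesterol=85,
                   carbohydrates=0, sugar=0, fiber=0, sodium=74),
        FoodRecord(name="beef", group="Meats", energy=250, protein=26,
                   total_lipids=15, saturated_fat=6.0, cholesterol=90,
                   carbohydrates=0, sugar=0, fiber=0, sodium=72),
    ]
    return FoodTable.from_records(recs)


@pytest.fixture(scope="session")
def synthetic_table():
    """19 groups x 20 foods at the default noise level."""
    return generate_food_table(default_group_profiles(), n_per_group=20,
                               noise_scale=0.1, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_food_matrix(rng, n, sparse_prob=0.3):
    """Random nonnegative (n, 9) nutrient matrix with realistic sparsity."""
    x = rng.gamma(shape=1.5, scale=30.0, size=(n, 9))
    mask = rng.random((n, 9)) < sparse_prob
    x[mask] = 0.0
    # keep every row nonzero
    x[np.all(x == 0, axis=1), 0] = 1.0
    return x
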