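"""Synthetic labeled food-composition tables.

Each of the 19 exchange categories is given a mean per-100 g (or per-100 mL)
nutrient profile reflecting its defining composition — high sugar for the
sugar groups, high protein and little fat for very-low-fat meats, near-zero
energy for free-energy foods, and so on.  Foods are drawn around the group
mean with multiplicative Gaussian noise,

    x = mean * (1 + noise_scale * cv * eps),  eps ~ N(0, 1) per component,

clipped at zero.  Multiplicative (rather than additive) noise keeps
zero-mean components exactly zero, preserving each group's sparsity pattern
(oils contain no sugar no matter the draw).  The raw aggregate columns are
reconstructed from the drawn sub-nutrients (carbohydrates = starch + sugar +
fiber, total lipids = saturated + unsaturated), so feature expansion inverts
the generator exactly.

The profile means are invented fixtures chosen for nutritional plausibility
and group separation; they are not derived from any published composition
database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .food_table_io import NUTRIENT_ORDER, FoodRecord, FoodTable

__all__ = ["GroupProfile", "default_group_profiles", "generate_food_table"]

#: Default within-group coefficient of variation per nutrient component.
#: Within an exchange group real foods vary substantially around the group
#: profile; 0.6 is a typical relative spread for composition data.
DEFAULT_CV = 0.6


@dataclass
class GroupProfile:
    """Mean nutrient profile of one exchange group.

    ``mean_vector`` follows :data:`~felkit.food_table_io.NUTRIENT_ORDER`:
    energy (kcal), protein (g), unsaturated fat (g), saturated fat (g),
    cholesterol (mg), starch (g), sugar (g), fiber (g), sodium (mg).
    """

    group: str
    mean_vector: tuple[float, ...]
    state: str = "solid"
    cv: tuple[float, ...] | float = DEFAULT_CV

    def __post_init__(self) -> None:
        if len(self.mean_vector) != len(NUTRIENT_ORDER):
            raise ValueError("mean_vector must have 9 components")
        if any(m < 0 for m in self.mean_vector):
            raise ValueError("profile means must be nonnegative")
        if not any(self.mean_vector):
            raise ValueError("profile mean vector must be nonzero")
        if np.isscalar(self.cv):
            self.cv = tuple([float(self.cv)] * len(NUTRIENT_ORDER))  # type: ignore[arg-type]
        if any(c < 0 for c in self.cv):  # type: ignore[union-attr]
            raise ValueError("coefficients of variation must be nonnegative")


def default_group_profiles() -> list[GroupProfile]:
    """Profiles for the 19 standard exchange categories.

    Mean vectors are per 100 g (solids) / 100 mL (liquids) in the order
    energy, protein, unsaturated fat, saturated fat, cholesterol, starch,
    sugar, fiber, sodium.
    """
    p = GroupProfile
    return [
        #                                  kcal  prot  unsat  sat  chol  starch sugar fiber  Na
        p("Oils and fats with protein",   (600,  18,   42,    8,    0,    8,    4,    8,    10)),
        p("Fat and oils",                 (880,  0.2,  70,   25,   20,    0,    0,    0,     5)),
        p("Free energy foods",            (  8,  0.5,  0.1,  0.05,  0,    0.3,  0.8,  0.5,  40), state="liquid"),
        p("Meat: Fish and poultry very high-fat content",
                                          (320,  17,   14,   11,   90,    0,    0,    0,   700)),
        p("Meat: Fish and poultry low-fat content",
                                          (150,  21,    4,    2.5, 70,    0,    0,    0,    90)),
        p("Meat: Fish and poultry high-fat content",
                                          (230,  18,   10,    6.5, 85,    0,    0,    0,   450)),
        p("Meat: Fish and poultry very low-fat content",
                                          (105,  23,    1.2,  0.6, 60,    0,    0,    0,    70)),
        p("Sugar with fat",               (480,   5,   12,   12,   10,   18,   48,    3,    80)),
        p("Sugar",                        (380,  0.3,  0.1,  0.1,   0,    2,   92,    0.2,  15)),
        p("Alcoholic beverage",           ( 90,  0.4,  0,    0,     0,    0.5,  4,    0,     8), state="liquid"),
        p("Cereal with high-fat content", (420,   7,   12,    6,   25,   48,   12,    3,   350)),
        p("Cereal with low-fat content",  (350,   9,    1.5,  0.5,  0,   68,    2.5,  5,   200)),
        p("Fruits",                       ( 55,  0.8,  0.25, 0.1,   0,    2,   10,    2.5,   2)),
        p("Dairy with sugar added",       ( 95,  3.2,  1.6,  1.6,  12,    1,   13,    0,    50), state="liquid"),
        p("Skim dairy products",          ( 35,  3.4,  0.06, 0.1,   2,    0,    5,    0,    45), state="liquid"),
        p("Whole dairy products",         ( 62,  3.2,  1.8,  1.9,  12,    0,    4.8,  0,    45), state="liquid"),
        p("Semi-skimmed dairy products",  ( 47,  3.3,  0.8,  1.0,   7,    0,    4.9,  0,    45), state="liquid"),
        p("Legumes",                      (120,  8.5,  0.5,  0.1,   0,   14,    0.5,  6.5,   5)),
        p("Vegetables",                   ( 28,  1.8,  0.15, 0.05,  0,    1.5,  3,    2.6,  20)),
    ]


def generate_food_table(
    profiles: list[GroupProfile] | None = None,
    n_per_group: int = 50,
    noise_scale: float = 0.1,
    seed: int = 0,
) -> FoodTable:
    """Draw a labeled synthetic food table around the group profiles.

    Deterministic given ``seed`` (NumPy PCG64 generator).  With
    ``noise_scale`` 0 every food equals its group mean, so groups are
    exactly their centroid directions.
    """
    if profiles is None:
        profiles = default_group_profiles()
    if len(profiles) == 0:
        raise ValueError("at least one group profile is required")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[FoodRecord] = []
    for prof in profiles:
        mean = np.asarray(prof.mean_vector, dtype=float)
        cv = np.asarray(prof.cv, dtype=float)
        eps = rng.standard_normal(size=(n_per_group, len(NUTRIENT_ORDER)))
        draws = np.clip(mean * (1.0 + noise_scale * cv * eps), 0.0, None)
        for i in range(n_per_group):
            e, prot, unsat, sat, chol, starch, sugar, fiber, sodium = draws[i]
            records.append(
                FoodRecord(
                    name=f"{prof.group} #{i + 1}",
                    group=prof.group,
                    state=prof.state,
                    energy=e,
                    protein=prot,
                    total_lipids=unsat + sat,
                    saturated_fat=sat,
                    cholesterol=chol,
                    carbohydrates=starch + sugar + fiber,
                    sugar=sugar,
                    fiber=fiber,
                    sodium=sodium,
                    starch=starch,
                )
            )
    return FoodTable.from_records(records)
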