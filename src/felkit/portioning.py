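"""Equivalent-portion calculation from group reference foods.

Each exchange group is anchored by a *key nutritional component*: the single
macronutrient amount one portion of the group must deliver (e.g. 15 g of
carbohydrate for fruits, 7 g of protein for meats, 5 g of fat for oils).
The equivalent portion of a food is the weight that delivers that amount:

    raw_grams = 100 * key_amount / nutrient_per_100g

High-moisture foods (fruits, vegetables, animal foods, cooked cereals and
legumes) are rounded to the nearest multiple of 5 g so the portion is usable
as a household measure; dry or raw foods (cereals, legumes) keep the exact
gram value.  A portion is acceptable when the delivered key amount stays
within the group mean +/- 2 standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .food_table_io import FoodRecord

__all__ = [
    "PortionSpec",
    "PortionResult",
    "NoFinitePortionError",
    "default_portion_specs",
    "equivalent_portion",
    "portion_tolerance_check",
    "HOUSEHOLD_ML",
]

#: Household-measure volume equivalences (display text only; grams are
#: authoritative).  A cup is 16 tablespoons; a tablespoon, 3 teaspoons.
HOUSEHOLD_ML = {"cup": 240.0, "tablespoon": 15.0, "teaspoon": 5.0}

KEY_NUTRIENTS = ("protein", "fat", "carbohydrates")


class NoFinitePortionError(ValueError):
    """The food contains none of the group's key nutrient."""


@dataclass(frozen=True)
class PortionSpec:
    """One group's reference food and key nutritional component."""

    group: str
    key_nutrient: str  # "protein" | "fat" | "carbohydrates"
    key_amount: float  # g per portion
    reference_food: str
    reference_portion: str
    secondary_nutrient: str | None = None
    secondary_amount: float | None = None

    def __post_init__(self) -> None:
        if self.key_nutrient not in KEY_NUTRIENTS:
            raise ValueError(f"unknown key nutrient {self.key_nutrient!r}")
        if self.key_amount <= 0:
            raise ValueError("key_amount must be > 0")


def default_portion_specs() -> list[PortionSpec]:
    """The eight standard exchange groups with their reference foods.

    Milk has two key components (9 g protein and 12 g carbohydrate); the
    portion is solved on protein and the carbohydrate delivery is reported
    for inspection.
    """
    return [
        PortionSpec("Vegetables", "carbohydrates", 4.0, "Carrot", "1/2 cup"),
        PortionSpec("Fruits", "carbohydrates", 15.0, "Apple", "One piece"),
        PortionSpec(
            "Cereals and by-products", "carbohydrates", 15.0, "Tortilla", "One piece"
        ),
        PortionSpec("Legumes", "protein", 8.0, "Cooked beans", "1/2 cup"),
        PortionSpec("Meats", "protein", 7.0, "Egg", "One piece"),
        PortionSpec(
            "Milk",
            "protein",
            9.0,
            "Milk",
            "One cup",
            secondary_nutrient="carbohydrates",
            secondary_amount=12.0,
        ),
        PortionSpec("Fat and oils", "fat", 5.0, "Oil", "One teaspoon"),
        PortionSpec("Sugar, honey, and candy", "carbohydrates", 10.0, "Sugar", "2 teaspoons"),
    ]


def _nutrient_density(record: FoodRecord, nutrient: str) -> float:
    if nutrient == "protein":
        return record.protein
    if nutrient == "fat":
        return record.total_lipids
    if nutrient == "carbohydrates":
        return record.carbohydrates
    raise ValueError(f"unknown key nutrient {nutrient!r}")


def round_to_five(grams: float) -> float:
    """Nearest multiple of 5, halves rounding up (32.5 -> 35)."""
    return 5.0 * math.floor(grams / 5.0 + 0.5)


@dataclass
class PortionResult:
    """An equivalent portion for one food."""

    food: str
    group: str
    raw_grams: float
    rounded_grams: float
    moisture_class: str  # "high_moisture" | "dry_raw"
    delivered_key_amount: float
    tolerance_flag: bool | None = None
    secondary_delivered: float | None = None
    household_text: str | None = None


def equivalent_portion(
    record: FoodRecord,
    spec: PortionSpec,
    moisture_class: str = "high_moisture",
    group_sd: float | None = None,
) -> PortionResult:
    """Portion of a food delivering its group's key nutrient amount.

    ``moisture_class`` selects the rounding rule; ``group_sd`` (standard
    deviation of delivered amounts within the group, in g), when given,
    sets the +/- 2 SD tolerance flag.
    """
    if moisture_class not in ("high_moisture", "dry_raw"):
        raise ValueError("moisture_class must be 'high_moisture' or 'dry_raw'")
    density = _nutrient_density(record, spec.key_nutrient)
    if density <= 0:
        raise NoFinitePortionError(
            f"{record.name!r} contains no {spec.key_nutrient}; "
            f"no finite portion delivers {spec.key_amount} g"
        )
    raw = 100.0 * spec.key_amount / density
    rounded = round_to_five(raw) if moisture_class == "high_moisture" else raw
    delivered = rounded * density / 100.0
    tolerance = None
    if group_sd is not None:
        tolerance = portion_tolerance_check(delivered, spec, group_sd)
    secondary = None
    if spec.secondary_nutrient is not None:
        secondary = rounded * _nutrient_density(record, spec.secondary_nutrient) / 100.0
    return PortionResult(
        food=record.name,
        group=spec.group,
        raw_grams=raw,
        rounded_grams=rounded,
        moisture_class=moisture_class,
        delivered_key_amount=delivered,
        tolerance_flag=tolerance,
        secondary_delivered=secondary,
        household_text=record.household_measure,
    )


def portion_tolerance_check(
    delivered: float, spec: PortionSpec, group_sd: float
) -> bool:
    """True iff the delivered amount lies within key_amount +/- 2 SD (inclusive)."""
    if group_sd < 0:
        raise ValueError("group_sd must be >= 0")
    return abs(delivered - spec.key_amount) <= 2.0 * group_sd
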