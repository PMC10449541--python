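"""Front-of-pack "excess nutrient" warning labels (Mexican NOM-051 cuts).

Five warning labels are evaluated per 100 g (solids) or 100 mL (liquids),
all with inclusive (>=) thresholds:

* excess calories — solids >= 275 kcal; liquids >= 70 kcal OR >= 8 g free
  sugar (the free-sugar clause belongs to the calorie label for liquids).
* excess sugars — free sugars contribute >= 10% of energy (4 kcal per g).
* excess saturated fat — saturated fat contributes >= 10% of energy
  (9 kcal per g).
* excess trans fat — trans fat contributes >= 1% of energy (9 kcal per g);
  skipped with a note when the trans-fat column is absent.
* excess sodium — >= 1 mg sodium per kcal OR >= 300 mg absolute; for
  calorie-free drinks (liquids under 5 kcal/100 mL by default) the cut is
  >= 45 mg.

Free sugars default to the total-sugar column when no separate free-sugar
column exists; composition tables rarely distinguish the two, and the
substitution (flagged in the evidence) is conservative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .food_table_io import FoodRecord, FoodTable

__all__ = [
    "LabelRuleSet",
    "LabelEvidence",
    "ExcessLabelSet",
    "label_food",
    "label_table",
    "KCAL_PER_G_SUGAR",
    "KCAL_PER_G_FAT",
]

#: Atwater energy-conversion factors used to turn gram amounts into energy shares.
KCAL_PER_G_SUGAR = 4.0
KCAL_PER_G_FAT = 9.0

LABEL_NAMES = (
    "excess_calories",
    "excess_sugars",
    "excess_saturated_fat",
    "excess_trans_fat",
    "excess_sodium",
)


@dataclass
class LabelRuleSet:
    """Cut points for the five warning labels (per 100 g / 100 mL)."""

    solid_energy_cut: float = 275.0  # kcal / 100 g
    liquid_energy_cut: float = 70.0  # kcal / 100 mL
    liquid_free_sugar_cut: float = 8.0  # g / 100 mL, feeds excess CALORIES
    sugar_energy_share_cut: float = 0.10
    satfat_energy_share_cut: float = 0.10
    transfat_energy_share_cut: float = 0.01
    sodium_per_kcal_cut: float = 1.0  # mg / kcal
    sodium_abs_cut: float = 300.0  # mg
    calorie_free_sodium_cut: float = 45.0  # mg
    calorie_free_energy_max: float = 5.0  # kcal/100 mL below which a drink is calorie-free

    def __post_init__(self) -> None:
        for name in (
            "solid_energy_cut",
            "liquid_energy_cut",
            "liquid_free_sugar_cut",
            "sodium_per_kcal_cut",
            "sodium_abs_cut",
            "calorie_free_sodium_cut",
            "calorie_free_energy_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "sugar_energy_share_cut",
            "satfat_energy_share_cut",
            "transfat_energy_share_cut",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be a share in (0, 1)")


@dataclass
class LabelEvidence:
    """The computed quantity and threshold behind one label decision."""

    quantity: float | None
    threshold: float
    rule: str
    applied: bool = True
    note: str = ""


@dataclass
class ExcessLabelSet:
    """The five boolean warning labels for one food, with evidence."""

    food: str
    excess_calories: bool
    excess_sugars: bool
    excess_saturated_fat: bool
    excess_trans_fat: bool
    excess_sodium: bool
    evidence: dict[str, LabelEvidence] = field(default_factory=dict)

    def as_dict(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in LABEL_NAMES}


def label_food(record: FoodRecord, rules: LabelRuleSet | None = None) -> ExcessLabelSet:
    """Apply the five cut-point rules to one food. All comparisons inclusive."""
    rules = rules or LabelRuleSet()
    energy = record.energy
    free_sugar = record.free_sugar
    sugar_note = ""
    if free_sugar is None:
        free_sugar = record.sugar
        sugar_note = "free sugars approximated by total sugar column"
    evidence: dict[str, LabelEvidence] = {}

    # excess calories
    if record.state == "solid":
        cal = energy >= rules.solid_energy_cut
        evidence["excess_calories"] = LabelEvidence(
            quantity=energy,
            threshold=rules.solid_energy_cut,
            rule="solid: energy >= cut (kcal/100 g)",
        )
    else:
        by_energy = energy >= rules.liquid_energy_cut
        by_sugar = free_sugar >= rules.liquid_free_sugar_cut
        cal = by_energy or by_sugar
        evidence["excess_calories"] = LabelEvidence(
            quantity=energy if (by_energy or not by_sugar) else free_sugar,
            threshold=rules.liquid_energy_cut if (by_energy or not by_sugar) else rules.liquid_free_sugar_cut,
            rule="liquid: energy >= cut (kcal/100 mL) OR free sugar >= cut (g/100 mL)",
            note=sugar_note,
        )

    # share-based rules need positive energy
    if energy > 0:
        sugar_share = KCAL_PER_G_SUGAR * free_sugar / energy
        sugars = sugar_share >= rules.sugar_energy_share_cut
        evidence["excess_sugars"] = LabelEvidence(
            quantity=sugar_share,
            threshold=rules.sugar_energy_share_cut,
            rule="4 kcal/g x free sugar / energy >= share cut",
            note=sugar_note,
        )
        sat_share = KCAL_PER_G_FAT * record.saturated_fat / energy
        satfat = sat_share >= rules.satfat_energy_share_cut
        evidence["excess_saturated_fat"] = LabelEvidence(
            quantity=sat_share,
            threshold=rules.satfat_energy_share_cut,
            rule="9 kcal/g x saturated fat / energy >= share cut",
        )
        if record.trans_fat is not None:
            trans_share = KCAL_PER_G_FAT * record.trans_fat / energy
            transfat = trans_share >= rules.transfat_energy_share_cut
            evidence["excess_trans_fat"] = LabelEvidence(
                quantity=trans_share,
                threshold=rules.transfat_energy_share_cut,
                rule="9 kcal/g x trans fat / energy >= share cut",
            )
        else:
            transfat = False
            evidence["excess_trans_fat"] = LabelEvidence(
                quantity=None,
                threshold=rules.transfat_energy_share_cut,
                rule="9 kcal/g x trans fat / energy >= share cut",
                applied=False,
                note="trans fat not reported; rule skipped",
            )
    else:
        sugars = satfat = transfat = False
        skipped = LabelEvidence(
            quantity=None,
            threshold=0.0,
            rule="energy-share rule",
            applied=False,
            note="zero-energy food; share-based rules skipped",
        )
        for name, cut in (
            ("excess_sugars", rules.sugar_energy_share_cut),
            ("excess_saturated_fat", rules.satfat_energy_share_cut),
            ("excess_trans_fat", rules.transfat_energy_share_cut),
        ):
            ev = LabelEvidence(**{**skipped.__dict__})
            ev.threshold = cut
            evidence[name] = ev

    # excess sodium
    sodium = record.sodium
    calorie_free_drink = (
        record.state == "liquid" and energy < rules.calorie_free_energy_max
    )
    if calorie_free_drink:
        sod = sodium >= rules.calorie_free_sodium_cut
        evidence["excess_sodium"] = LabelEvidence(
            quantity=sodium,
            threshold=rules.calorie_free_sodium_cut,
            rule="calorie-free drink: sodium >= cut (mg)",
        )
    else:
        by_ratio = energy > 0 and (sodium / energy) >= rules.sodium_per_kcal_cut
        by_abs = sodium >= rules.sodium_abs_cut
        sod = by_ratio or by_abs
        if by_ratio and not by_abs:
            evidence["excess_sodium"] = LabelEvidence(
                quantity=sodium / energy,
                threshold=rules.sodium_per_kcal_cut,
                rule="sodium (mg) / energy (kcal) >= cut",
            )
        else:
            evidence["excess_sodium"] = LabelEvidence(
                quantity=sodium,
                threshold=rules.sodium_abs_cut,
                rule="sodium >= absolute cut (mg) OR sodium/energy >= per-kcal cut",
            )

    return ExcessLabelSet(
        food=record.name,
        excess_calories=cal,
        excess_sugars=sugars,
        excess_saturated_fat=satfat,
        excess_trans_fat=transfat,
        excess_sodium=sod,
        evidence=evidence,
    )


def label_table(
    table: FoodTable, rules: LabelRuleSet | None = None
) -> tuple[list[ExcessLabelSet], dict[str, int]]:
    """Label every food in a table; returns per-food labels (order-preserving)
    plus summary counts per label."""
    rules = rules or LabelRuleSet()
    labels = [label_food(rec, rules) for rec in table.records]
    summary: Counter[str] = Counter({name: 0 for name in LABEL_NAMES})
    for ls in labels:
        for name, value in ls.as_dict().items():
            if value:
                summary[name] += 1
    return labels, dict(summary)
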