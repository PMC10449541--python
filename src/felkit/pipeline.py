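"""End-to-end exchange-list pipeline: normalize -> classify -> rank
equivalents -> warning labels -> equivalent portion.

Given any composition table the pipeline fits the dimensionless space and a
classifier on a labeled reference (the input itself when labeled, a
reference CSV otherwise, or the built-in synthetic table as a last resort),
then emits a per-food report: the top candidate groups, the closest
equivalent foods with their gram amounts, the five excess-nutrient labels,
and the equivalent portion implied by the predicted group's key nutrient.

All randomness flows from the single config seed and reports carry a config
echo, so a rerun with the same config reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .classifiers import fit_mlp, fit_skm, predict_mlp, predict_skm, stratified_cv
from .excess_labeling import LabelRuleSet, label_food
from .food_table_io import FoodTable, expand_features, read_food_table
from .normalization import fit_dimensionless, project
from .portioning import (
    NoFinitePortionError,
    default_portion_specs,
    equivalent_portion,
)
from .similarity import DegenerateVectorError, rank_equivalents
from .synthetic import generate_food_table

__all__ = ["RunConfig", "run_pipeline", "CATEGORY_PORTION_MAP"]

REPORT_VERSION = 1

#: Exchange category -> (portion-spec group, moisture class).  High-moisture
#: categories (fruits, vegetables, animal foods, dairy, cooked legumes) get
#: portions rounded to 5 g; dry or raw foods keep exact grams.
CATEGORY_PORTION_MAP: dict[str, tuple[str, str]] = {
    "Oils and fats with protein": ("Fat and oils", "dry_raw"),
    "Fat and oils": ("Fat and oils", "dry_raw"),
    "Meat: Fish and poultry very high-fat content": ("Meats", "high_moisture"),
    "Meat: Fish and poultry low-fat content": ("Meats", "high_moisture"),
    "Meat: Fish and poultry high-fat content": ("Meats", "high_moisture"),
    "Meat: Fish and poultry very low-fat content": ("Meats", "high_moisture"),
    "Sugar with fat": ("Sugar, honey, and candy", "dry_raw"),
    "Sugar": ("Sugar, honey, and candy", "dry_raw"),
    "Cereal with high-fat content": ("Cereals and by-products", "dry_raw"),
    "Cereal with low-fat content": ("Cereals and by-products", "dry_raw"),
    "Fruits": ("Fruits", "high_moisture"),
    "Dairy with sugar added": ("Milk", "high_moisture"),
    "Skim dairy products": ("Milk", "high_moisture"),
    "Whole dairy products": ("Milk", "high_moisture"),
    "Semi-skimmed dairy products": ("Milk", "high_moisture"),
    "Legumes": ("Legumes", "high_moisture"),
    "Vegetables": ("Vegetables", "high_moisture"),
    # "Free energy foods" and "Alcoholic beverage" carry no key nutrient.
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON keys mirror the fields)."""

    input: str | None = None  # CSV path; None -> built-in synthetic table
    schema: dict[str, str] = field(default_factory=dict)
    reference: str | None = None  # labeled CSV to fit on when input is unlabeled
    model: str = "skm"  # "skm" | "mlp"
    k: int = 5  # equivalents per food
    top_groups: int = 3
    same_group_only: bool = False
    cv_splits: int = 0  # 0 skips the cross-validation section
    seed: int = 0
    label_rules: dict[str, float] = field(default_factory=dict)
    mlp: dict[str, Any] = field(default_factory=dict)

    def echo(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _load_table(config: RunConfig) -> FoodTable:
    if config.input is None:
        return generate_food_table(seed=config.seed)
    return read_food_table(config.input, schema=config.schema or None)


def _fit_table(config: RunConfig, input_table: FoodTable) -> tuple[FoodTable, str]:
    if input_table.labels is not None and input_table.n > 1:
        return input_table, "input"
    if config.reference is not None:
        ref = read_food_table(config.reference, schema=config.schema or None)
        if ref.labels is None:
            raise ValueError("reference table must be fully labeled")
        return ref, "reference"
    return generate_food_table(seed=config.seed), "builtin_synthetic"


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full pipeline and return the machine-readable report."""
    input_table = _load_table(config)
    fit_table, fit_source = _fit_table(config, input_table)
    dim = fit_dimensionless(fit_table)
    rules = LabelRuleSet(**config.label_rules)
    specs = {s.group: s for s in default_portion_specs()}

    if config.model == "skm":
        skm = fit_skm(dim, fit_table.labels)
        classify = lambda feat9, mag, true: predict_skm(skm, feat9, true)  # noqa: E731
    elif config.model == "mlp":
        mlp = fit_mlp(dim, fit_table.labels, seed=config.seed, **config.mlp)
        classify = lambda feat9, mag, true: predict_mlp(  # noqa: E731
            mlp, np.append(feat9, mag), true
        )
    else:
        raise ValueError(f"unknown model {config.model!r}")

    foods: list[dict[str, Any]] = []
    warnings_log = [dataclasses.asdict(ev) for ev in input_table.report]
    n_failed = 0
    labeled = input_table.labels is not None
    predictions = []
    for rec in input_table.records:
        entry: dict[str, Any] = {"name": rec.name, "group": rec.group, "state": rec.state}
        try:
            raw_vec, clip_events = expand_features(rec)
            dim_vec, mag = project(raw_vec, dim.scale)
            pred = classify(dim_vec, mag, rec.group if labeled else None)
            predictions.append(pred)
            entry["top_groups"] = pred.ranking[: config.top_groups]
            if labeled:
                entry["true_group_rank"] = pred.true_group_rank
            try:
                eqs = rank_equivalents(
                    rec,
                    fit_table,
                    dim.scale,
                    k=config.k,
                    same_group_only=config.same_group_only,
                    target_group=rec.group or pred.top,
                )
                entry["equivalents"] = [
                    {
                        "candidate": e.candidate_name,
                        "similarity": e.similarity,
                        "alpha": e.alpha,
                        "grams": e.grams,
                    }
                    for e in eqs
                ]
            except DegenerateVectorError as exc:
                entry["equivalents"] = []
                warnings_log.append({"food": rec.name, "warning": str(exc)})
            labels = label_food(rec, rules)
            entry["excess_labels"] = labels.as_dict()
            portion_group = rec.group if rec.group in CATEGORY_PORTION_MAP else pred.top
            mapped = CATEGORY_PORTION_MAP.get(portion_group)
            if mapped is not None:
                spec_group, moisture = mapped
                try:
                    portion = equivalent_portion(rec, specs[spec_group], moisture)
                    entry["portion"] = {
                        "spec_group": spec_group,
                        "key_nutrient": specs[spec_group].key_nutrient,
                        "key_amount_g": specs[spec_group].key_amount,
                        "raw_grams": portion.raw_grams,
                        "rounded_grams": portion.rounded_grams,
                        "delivered_key_amount": portion.delivered_key_amount,
                    }
                except NoFinitePortionError as exc:
                    entry["portion"] = None
                    warnings_log.append({"food": rec.name, "warning": str(exc)})
            else:
                entry["portion"] = None
        except Exception as exc:  # stage error: mark food failed, continue
            entry["error"] = str(exc)
            n_failed += 1
        foods.append(entry)

    report: dict[str, Any] = {
        "report_version": REPORT_VERSION,
        "config": config.echo(),
        "fit_source": fit_source,
        "n_foods": input_table.n,
        "n_failed": n_failed,
        "foods": foods,
        "warnings": warnings_log,
    }
    if labeled and predictions:
        ranks = np.array([p.true_group_rank for p in predictions if p.true_group_rank])
        report["accuracy"] = {
            "top1": float(np.mean(ranks <= 1)),
            f"top{config.top_groups}": float(np.mean(ranks <= config.top_groups)),
        }
    if config.cv_splits >= 2 and labeled:
        cv = stratified_cv(
            input_table, config.model, n_splits=config.cv_splits, seed=config.seed
        )
        report["cross_validation"] = {
            "n_splits": config.cv_splits,
            "fold_accuracies": cv.fold_accuracies,
            "mean_accuracy": cv.mean_accuracy,
        }
    return report
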