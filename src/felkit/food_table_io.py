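"""Food-composition table I/O and nutrient feature expansion.

A food-composition table stores, per food, the nutrient content of 100 g
(solids) or 100 mL (liquids): energy (kcal), protein (g), total lipids (g),
saturated fat (g), cholesterol (mg), carbohydrates (g), sugar (g), fiber (g)
and sodium (mg).  For vector analysis the two aggregate columns are broken
into sub-nutrients,

    carbohydrates = starch + sugar + fiber
    total lipids  = unsaturated fat + saturated fat

so every food becomes a 9-component nutrient vector whose fixed component
order is :data:`NUTRIENT_ORDER`.  Missing nutrient values are imputed as 0
(a nutrient left off a label is treated as absent); negative derived
sub-nutrients are clipped to 0 with a logged warning, since published
composition tables routinely contain small internal inconsistencies.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NUTRIENT_ORDER",
    "DEFAULT_SCHEMA",
    "FoodRecord",
    "FoodTable",
    "TableEvent",
    "SchemaError",
    "ValidationError",
    "EmptyInputError",
    "expand_features",
    "read_food_table",
    "records_to_dataframe",
    "write_food_table",
    "write_results",
    "read_results",
]

#: Fixed component order of the 9-dimensional nutrient vector, shared by the
#: whole codebase (normalization, similarity, classifiers all index into it).
NUTRIENT_ORDER: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "unsaturated_fat_g",
    "saturated_fat_g",
    "cholesterol_mg",
    "starch_g",
    "sugar_g",
    "fiber_g",
    "sodium_mg",
)

#: Default CSV header.  ``read_food_table`` accepts any header through a
#: ``schema`` mapping of logical field name -> actual column name.
DEFAULT_SCHEMA: dict[str, str] = {
    "name": "name",
    "group": "group",
    "state": "state",
    "energy": "energy_kcal",
    "protein": "protein_g",
    "total_lipids": "total_lipids_g",
    "saturated_fat": "saturated_fat_g",
    "trans_fat": "trans_fat_g",
    "cholesterol": "cholesterol_mg",
    "carbohydrates": "carbohydrates_g",
    "sugar": "sugar_g",
    "free_sugar": "free_sugar_g",
    "fiber": "fiber_g",
    "sodium": "sodium_mg",
    "starch": "starch_g",
    "household_measure": "household_measure",
}

#: Logical fields that must be present in every input table.
MANDATORY_FIELDS: tuple[str, ...] = (
    "name",
    "energy",
    "protein",
    "total_lipids",
    "saturated_fat",
    "cholesterol",
    "carbohydrates",
    "sugar",
    "fiber",
    "sodium",
)

_NUTRIENT_FIELDS: tuple[str, ...] = (
    "energy",
    "protein",
    "total_lipids",
    "saturated_fat",
    "trans_fat",
    "cholesterol",
    "carbohydrates",
    "sugar",
    "free_sugar",
    "fiber",
    "sodium",
    "starch",
)

#: Tolerance for the internal-consistency checks sugar + fiber <= carbohydrates
#: and saturated fat <= total lipids (grams).
CONSISTENCY_TOL = 1e-6


class SchemaError(ValueError):
    """A mandatory column is missing from the input table."""


class ValidationError(ValueError):
    """A nutrient value violates a hard constraint (e.g. negative)."""


class EmptyInputError(ValueError):
    """The input table contains no food rows."""


@dataclass
class TableEvent:
    """One logged imputation or clipping event for a table row."""

    row: int
    food: str
    column: str
    action: str  # "imputed_zero" | "clipped_negative" | "inconsistent"
    detail: str = ""


@dataclass
class FoodRecord:
    """Raw per-100 g (solids) or per-100 mL (liquids) nutrient values."""

    name: str
    energy: float
    protein: float
    total_lipids: float
    saturated_fat: float
    cholesterol: float
    carbohydrates: float
    sugar: float
    fiber: float
    sodium: float
    group: str | None = None
    state: str = "solid"  # "solid" | "liquid"
    trans_fat: float | None = None
    starch: float | None = None
    free_sugar: float | None = None
    household_measure: str | None = None

    def __post_init__(self) -> None:
        if self.state not in ("solid", "liquid"):
            raise ValidationError(
                f"food {self.name!r}: state must be 'solid' or 'liquid', got {self.state!r}"
            )
        for fname in _NUTRIENT_FIELDS:
            value = getattr(self, fname)
            if value is None:
                continue
            if not math.isfinite(value):
                raise ValidationError(f"food {self.name!r}: {fname} is not finite")
            if value < 0:
                raise ValidationError(
                    f"food {self.name!r}: {fname} is negative ({value})"
                )


def expand_features(record: FoodRecord) -> tuple[np.ndarray, list[TableEvent]]:
    """Expand a raw record into the ordered 9-component nutrient vector.

    Starch is derived as ``carbohydrates - sugar - fiber`` when no explicit
    starch value is given, and unsaturated fat as
    ``total_lipids - saturated_fat``.  Negative derived values are clipped to
    0 and reported as clip events (a warning, not an error).

    Returns the vector (in :data:`NUTRIENT_ORDER` order) and the list of
    clipping events.
    """
    events: list[TableEvent] = []
    if record.starch is not None:
        starch = record.starch
    else:
        starch = record.carbohydrates - record.sugar - record.fiber
        if starch < 0:
            events.append(
                TableEvent(
                    row=-1,
                    food=record.name,
                    column="starch_g",
                    action="clipped_negative",
                    detail=f"carbohydrates - sugar - fiber = {starch:.6g} < 0",
                )
            )
            starch = 0.0
    unsat = record.total_lipids - record.saturated_fat
    if unsat < 0:
        events.append(
            TableEvent(
                row=-1,
                food=record.name,
                column="unsaturated_fat_g",
                action="clipped_negative",
                detail=f"total_lipids - saturated_fat = {unsat:.6g} < 0",
            )
        )
        unsat = 0.0
    vec = np.array(
        [
            record.energy,
            record.protein,
            unsat,
            record.saturated_fat,
            record.cholesterol,
            starch,
            record.sugar,
            record.fiber,
            record.sodium,
        ],
        dtype=float,
    )
    return vec, events


@dataclass
class FoodTable:
    """An ordered collection of foods plus their expanded nutrient vectors.

    ``vectors`` is an (N, 9) matrix whose rows correspond 1:1, in order,
    with ``records``.  ``report`` collects every imputation / clipping event
    that occurred while building the table.
    """

    records: list[FoodRecord]
    vectors: np.ndarray
    report: list[TableEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise EmptyInputError("a FoodTable must contain at least one food")
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (len(self.records), len(NUTRIENT_ORDER)):
            raise ValueError(
                f"vectors shape {self.vectors.shape} does not match "
                f"{len(self.records)} records x {len(NUTRIENT_ORDER)} nutrients"
            )

    @classmethod
    def from_records(cls, records: Sequence[FoodRecord]) -> "FoodTable":
        if len(records) == 0:
            raise EmptyInputError("no food records supplied")
        vectors = np.empty((len(records), len(NUTRIENT_ORDER)), dtype=float)
        report: list[TableEvent] = []
        for i, rec in enumerate(records):
            vec, events = expand_features(rec)
            vectors[i] = vec
            for ev in events:
                ev.row = i
                report.append(ev)
        return cls(records=list(records), vectors=vectors, report=report)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    @property
    def labels(self) -> list[str] | None:
        """Group labels per row, or None when any row is unlabeled."""
        groups = [r.group for r in self.records]
        if any(g is None for g in groups):
            return None
        return groups  # type: ignore[return-value]


def _get(row: pd.Series, schema: Mapping[str, str], field_name: str) -> Any:
    col = schema.get(field_name)
    if col is None or col not in row.index:
        return None
    value = row[col]
    if pd.isna(value):
        return None
    return value


def read_food_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> FoodTable:
    """Read a food-composition CSV into a :class:`FoodTable`.

    ``schema`` maps logical field names (``energy``, ``protein``, ...) to the
    actual CSV column names; unspecified fields fall back to
    :data:`DEFAULT_SCHEMA`.  Missing values in any nutrient column are imputed
    as 0 and logged in the table's report.  Negative nutrient values raise
    :class:`ValidationError` naming the row and column.
    """
    merged = dict(DEFAULT_SCHEMA)
    if schema:
        merged.update(schema)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty input file") from exc
    if len(df) == 0:
        raise EmptyInputError(f"{path}: table has a header but no food rows")

    missing = [
        merged[f] for f in MANDATORY_FIELDS if merged[f] not in df.columns
    ]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")

    records: list[FoodRecord] = []
    report: list[TableEvent] = []
    for i, (_, row) in enumerate(df.iterrows()):
        kwargs: dict[str, Any] = {}
        name = _get(row, merged, "name")
        name = str(name) if name is not None else f"row {i}"
        kwargs["name"] = name
        group = _get(row, merged, "group")
        kwargs["group"] = str(group) if group is not None else None
        state = _get(row, merged, "state")
        kwargs["state"] = str(state) if state is not None else "solid"
        hm = _get(row, merged, "household_measure")
        kwargs["household_measure"] = str(hm) if hm is not None else None
        for fname in _NUTRIENT_FIELDS:
            raw = _get(row, merged, fname)
            optional = fname in ("trans_fat", "starch", "free_sugar")
            if raw is None:
                if optional:
                    # blank optional sub-nutrient means "absent" (starch is
                    # then derived, trans-fat rules skipped), not zero
                    kwargs[fname] = None
                    continue
                report.append(
                    TableEvent(i, name, merged[fname], "imputed_zero")
                )
                kwargs[fname] = 0.0
                continue
            value = float(raw)
            if value < 0:
                raise ValidationError(
                    f"{path}: negative value {value} in column "
                    f"{merged[fname]!r}, row {i} ({name!r})"
                )
            kwargs[fname] = value
        rec = FoodRecord(**kwargs)
        # internal-consistency flags (then handled by clipping in expansion)
        if rec.sugar + rec.fiber > rec.carbohydrates + CONSISTENCY_TOL:
            report.append(
                TableEvent(
                    i,
                    name,
                    merged["carbohydrates"],
                    "inconsistent",
                    f"sugar + fiber = {rec.sugar + rec.fiber:.6g} exceeds "
                    f"carbohydrates = {rec.carbohydrates:.6g}",
                )
            )
        if rec.saturated_fat > rec.total_lipids + CONSISTENCY_TOL:
            report.append(
                TableEvent(
                    i,
                    name,
                    merged["total_lipids"],
                    "inconsistent",
                    f"saturated fat = {rec.saturated_fat:.6g} exceeds "
                    f"total lipids = {rec.total_lipids:.6g}",
                )
            )
        records.append(rec)

    table = FoodTable.from_records(records)
    table.report = report + table.report
    return table


def records_to_dataframe(records: Iterable[FoodRecord]) -> pd.DataFrame:
    """Serialize records to a DataFrame using the default CSV header."""
    rows = []
    for r in records:
        rows.append(
            {
                "name": r.name,
                "group": r.group,
                "state": r.state,
                "energy_kcal": r.energy,
                "protein_g": r.protein,
                "total_lipids_g": r.total_lipids,
                "saturated_fat_g": r.saturated_fat,
                "trans_fat_g": r.trans_fat,
                "cholesterol_mg": r.cholesterol,
                "carbohydrates_g": r.carbohydrates,
                "sugar_g": r.sugar,
                "free_sugar_g": r.free_sugar,
                "fiber_g": r.fiber,
                "sodium_mg": r.sodium,
                "starch_g": r.starch,
                "household_measure": r.household_measure,
            }
        )
    return pd.DataFrame(rows)


def write_food_table(table: FoodTable, path: str | Path) -> None:
    """Write a table back to CSV in the default schema."""
    records_to_dataframe(table.records).to_csv(path, index=False)


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def write_results(results: Any, path: str | Path, format: str = "json") -> None:
    """Write a result collection (dataclasses, dicts, lists) to CSV or JSON.

    JSON output round-trips through :func:`read_results` without loss.
    """
    if results is None:
        raise ValueError("results must not be None")
    plain = _to_plain(results)
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(plain, fh, indent=2, sort_keys=False)
            fh.write("\n")
    elif format == "csv":
        if isinstance(plain, dict):
            plain = [plain]
        pd.DataFrame(plain).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")


def read_results(path: str | Path) -> Any:
    """Read back a JSON result file written by :func:`write_results`."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
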