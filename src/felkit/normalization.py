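"""Dimensionless transform of nutrient tables.

Nutrient columns live on wildly different scales (kcal, g, mg), so raw
vectors cannot be compared directly: a 50 kcal difference is not comparable
to 50 g of saturated fat.  The transform rescales each nutrient column of an
N-food table by its column mean,

    x_bar[i, j] = N * x[i, j] / sum_i x[i, j]

so every non-degenerate column has mean exactly 1 and all entries are
dimensionless.  Columns whose sum is zero (a nutrient absent from every
food) are mapped to all-zeros and flagged as degenerate rather than raising.

New foods are projected into an already-fitted space with the frozen
reference column sums — classifying one food must not move the space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .food_table_io import NUTRIENT_ORDER, FoodTable

__all__ = ["ScaleFactors", "DimensionlessTable", "fit_dimensionless", "project"]


@dataclass
class ScaleFactors:
    """Frozen per-column sums of a reference table, for projection.

    ``column_sums[j]`` is the sum of nutrient j over the N reference foods;
    ``degenerate[j]`` marks all-zero columns, which project to 0.
    """

    column_sums: np.ndarray  # shape (9,)
    n: int
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.column_sums = np.asarray(self.column_sums, dtype=float)
        if self.column_sums.shape != (len(NUTRIENT_ORDER),):
            raise ValueError("column_sums must have one entry per nutrient")
        if self.n < 1:
            raise ValueError("reference table must contain at least one food")
        if np.any(self.column_sums < 0):
            raise ValueError("column sums must be nonnegative")
        if self.degenerate is None:
            self.degenerate = self.column_sums == 0
        self.degenerate = np.asarray(self.degenerate, dtype=bool)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "nutrients": list(NUTRIENT_ORDER),
                "column_sums": self.column_sums.tolist(),
                "n": self.n,
                "degenerate": self.degenerate.tolist(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "ScaleFactors":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text(encoding="utf-8")
        data = json.loads(text)
        return cls(
            column_sums=np.array(data["column_sums"], dtype=float),
            n=int(data["n"]),
            degenerate=np.array(data["degenerate"], dtype=bool),
        )


@dataclass
class DimensionlessTable:
    """A table transformed to dimensionless space.

    ``matrix`` holds the transformed (N, 9) values, ``scale`` the frozen
    column sums needed to project new foods, and ``magnitudes`` the per-row
    Euclidean norm of the dimensionless vector (used as an extra input
    feature by the neural-network classifier).
    """

    matrix: np.ndarray
    scale: ScaleFactors
    magnitudes: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def fit_dimensionless(table: FoodTable) -> DimensionlessTable:
    """Fit the dimensionless transform on a food table.

    Every non-degenerate column of the result has mean 1; degenerate
    (all-zero) columns map to zeros and are flagged in the scale factors.
    """
    x = np.asarray(table.vectors, dtype=float)
    if np.any(x < 0):
        raise ValueError("nutrient vectors must be nonnegative")
    sums = x.sum(axis=0)
    degenerate = sums == 0
    scale = ScaleFactors(column_sums=sums, n=table.n, degenerate=degenerate)
    safe = np.where(degenerate, 1.0, sums)
    matrix = table.n * x / safe
    matrix[:, degenerate] = 0.0
    magnitudes = np.linalg.norm(matrix, axis=1)
    return DimensionlessTable(matrix=matrix, scale=scale, magnitudes=magnitudes)


def project(
    vector: np.ndarray,
    scale: ScaleFactors,
    magnitude_source: str = "dimensionless",
) -> tuple[np.ndarray, float]:
    """Project a raw nutrient vector into a fitted dimensionless space.

    Component j maps to ``n * x[j] / column_sums[j]`` (0 for degenerate
    columns).  Returns the dimensionless 9-vector and its magnitude; with
    ``magnitude_source="raw"`` the magnitude is instead the Euclidean norm of
    the raw input vector (an alternative definition of the extra classifier
    feature, exposed for comparison).
    """
    x = np.asarray(vector, dtype=float)
    if x.shape != (len(NUTRIENT_ORDER),):
        raise ValueError(f"expected a {len(NUTRIENT_ORDER)}-vector, got shape {x.shape}")
    if np.any(x < 0):
        raise ValueError("nutrient vector components must be nonnegative")
    safe = np.where(scale.degenerate, 1.0, scale.column_sums)
    out = scale.n * x / safe
    out = np.where(scale.degenerate, 0.0, out)
    if magnitude_source == "dimensionless":
        magnitude = float(np.linalg.norm(out))
    elif magnitude_source == "raw":
        magnitude = float(np.linalg.norm(x))
    else:
        raise ValueError("magnitude_source must be 'dimensionless' or 'raw'")
    return out, magnitude


def project_matrix(
    vectors: np.ndarray,
    scale: ScaleFactors,
    magnitude_source: str = "dimensionless",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`project` over the rows of an (N, 9) matrix."""
    x = np.asarray(vectors, dtype=float)
    if np.any(x < 0):
        raise ValueError("nutrient vector components must be nonnegative")
    safe = np.where(scale.degenerate, 1.0, scale.column_sums)
    out = scale.n * x / safe
    out[:, scale.degenerate] = 0.0
    if magnitude_source == "dimensionless":
        mags = np.linalg.norm(out, axis=1)
    elif magnitude_source == "raw":
        mags = np.linalg.norm(x, axis=1)
    else:
        raise ValueError("magnitude_source must be 'dimensionless' or 'raw'")
    return out, mags
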