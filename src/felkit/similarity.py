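"""Cosine similarity, equivalence factors and two-food blends.

Two foods A and B (per-100 g nutrient vectors) are compared by the cosine of
the angle between them, Sim(A, B) = <A, B> / (|A||B|): similarity of nutrient
*concentration profile*, independent of amount.  The equivalence factor

    alpha = |A| cos(theta_AB) / |B| = <A, B> / |B|^2

is the scalar multiple of B that best approximates A in the least-squares
sense, so 100 * alpha grams of B stands in for 100 g of A.  Both quantities
are computed in the dimensionless space, where nutrient units cancel; the
raw-space factor is reported alongside for the gram output.

A target profile can also be matched by a nonnegative blend of two foods,
C ~ alpha*A + beta*B, solved by constrained least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .food_table_io import FoodRecord, FoodTable, expand_features
from .normalization import ScaleFactors, project, project_matrix

__all__ = [
    "DegenerateVectorError",
    "EquivalenceResult",
    "BlendResult",
    "cosine_similarity",
    "equivalence_factor",
    "rank_equivalents",
    "blend_factors",
]


class DegenerateVectorError(ValueError):
    """A zero (or effectively zero) vector where a direction is required."""


def _check_nonzero(v: np.ndarray, label: str) -> float:
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise DegenerateVectorError(f"{label} is a zero vector")
    return norm


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two nonnegative nutrient vectors.

    Clamped to [0, 1] against floating-point overshoot (nonnegative vectors
    cannot have a negative cosine).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = _check_nonzero(u, "first vector")
    nv = _check_nonzero(v, "second vector")
    sim = float(np.dot(u, v) / (nu * nv))
    return min(1.0, max(0.0, sim))


def equivalence_factor(a: np.ndarray, b: np.ndarray) -> float:
    """Scalar alpha minimizing |A - alpha*B|: alpha = <A, B> / |B|^2.

    Equivalently |A| cos(theta_AB) / |B|, the least-squares projection
    coefficient of A onto the direction of B.  Both vectors must live in the
    same (dimensionless) space.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    nb = _check_nonzero(b, "candidate vector B")
    return float(np.dot(a, b) / (nb * nb))


@dataclass
class EquivalenceResult:
    """One ranked candidate equivalent for a target food.

    ``alpha`` is the dimensionless-space equivalence factor and ``grams``
    = 100 * alpha the equivalent amount of the candidate.  ``alpha_raw`` /
    ``grams_raw`` repeat the computation on the raw per-100 g vectors, where
    the unscaled nutrient units weight the fit differently; both are reported
    because neither dominates the other for every use.
    """

    target_name: str
    candidate_name: str
    similarity: float
    alpha: float
    grams: float
    alpha_raw: float
    grams_raw: float
    candidate_group: str | None = None


def rank_equivalents(
    target: FoodRecord | np.ndarray,
    table: FoodTable,
    scale: ScaleFactors,
    k: int = 5,
    same_group_only: bool = False,
    target_group: str | None = None,
) -> list[EquivalenceResult]:
    """Rank the table's foods by similarity to a target food.

    Candidates are sorted by cosine similarity in dimensionless space,
    descending, ties broken by table order; the target itself (matched by
    name) is excluded.  Each result carries the equivalence factor and the
    equivalent grams of candidate food.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(target, FoodRecord):
        raw_target, _ = expand_features(target)
        target_name = target.name
        if target_group is None:
            target_group = target.group
    else:
        raw_target = np.asarray(target, dtype=float)
        target_name = "<vector>"
    dim_target, _ = project(raw_target, scale)
    _check_nonzero(dim_target, "target vector (dimensionless)")

    if same_group_only:
        if table.labels is None:
            raise ValueError("same_group_only requires a fully labeled table")
        if target_group is None:
            raise ValueError("same_group_only requires the target's group")

    dim_matrix, _ = project_matrix(table.vectors, scale)
    results: list[EquivalenceResult] = []
    for i, rec in enumerate(table.records):
        if rec.name == target_name:
            continue
        if same_group_only and rec.group != target_group:
            continue
        cand_dim = dim_matrix[i]
        if not np.any(cand_dim):
            continue  # degenerate candidate cannot be ranked
        sim = cosine_similarity(dim_target, cand_dim)
        alpha = equivalence_factor(dim_target, cand_dim)
        cand_raw = table.vectors[i]
        alpha_raw = (
            equivalence_factor(raw_target, cand_raw) if np.any(cand_raw) else 0.0
        )
        results.append(
            EquivalenceResult(
                target_name=target_name,
                candidate_name=rec.name,
                similarity=sim,
                alpha=alpha,
                grams=100.0 * alpha,
                alpha_raw=alpha_raw,
                grams_raw=100.0 * alpha_raw,
                candidate_group=rec.group,
            )
        )
    # stable sort preserves input order among ties
    results.sort(key=lambda r: -r.similarity)
    return results[:k]


@dataclass
class BlendResult:
    """Nonnegative least-squares coefficients for C ~ alpha*A + beta*B."""

    alpha: float
    beta: float
    residual_norm: float


def blend_factors(
    c: np.ndarray, a: np.ndarray, b: np.ndarray, parallel_tol: float = 1e-12
) -> BlendResult:
    """Best nonnegative two-food blend of A and B approximating target C.

    Solves min |C - alpha*A - beta*B|^2 with alpha, beta >= 0 by the 2x2
    normal equations, falling back to the nonnegativity boundary (one
    coefficient zero) when the unconstrained optimum leaves the quadrant.
    Raises :class:`DegenerateVectorError` when A and B are parallel — use
    :func:`equivalence_factor` with a single food instead.
    """
    c = np.asarray(c, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = _check_nonzero(a, "food A")
    nb = _check_nonzero(b, "food B")
    aa = float(np.dot(a, a))
    bb = float(np.dot(b, b))
    ab = float(np.dot(a, b))
    det = aa * bb - ab * ab
    if det <= parallel_tol * aa * bb:
        raise DegenerateVectorError(
            "foods A and B are (near-)parallel; a two-food blend is "
            "ill-posed — use the single-food equivalence factor instead"
        )
    ca = float(np.dot(c, a))
    cb = float(np.dot(c, b))
    alpha = (ca * bb - cb * ab) / det
    beta = (cb * aa - ca * ab) / det
    if alpha < 0 or beta < 0:
        # active-set fallback: best single-food fits on each boundary edge
        cand = [
            (max(0.0, ca / aa), 0.0),
            (0.0, max(0.0, cb / bb)),
        ]
        best = min(
            cand, key=lambda t: float(np.linalg.norm(c - t[0] * a - t[1] * b))
        )
        alpha, beta = best
    residual = float(np.linalg.norm(c - alpha * a - beta * b))
    return BlendResult(alpha=alpha, beta=beta, residual_norm=residual)
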