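"""Exchange-group classifiers: spherical-k-means centroids and an MLP.

The centroid classifier represents each exchange group j by a unit-norm
vector W_j in dimensionless nutrient space — the mean of the group's
dimensionless food vectors, normalized — and assigns a food to

    argmax_j Sim(A, W_j)

i.e. the group whose centroid direction is closest in cosine similarity.
Because the group labels are known, centroid placement is supervised (group
means); no iterative reassignment is run.  This is equivalent to a
single-layer linear network with unit-normalized weight rows and no
activation; relaxing those constraints gives the multilayer-perceptron
classifier, trained on a 10-feature input (the 9 dimensionless components
plus the vector's Euclidean magnitude, which restores the amount information
the dimensionless transform discards).

Predictions are full rankings of groups, so accuracy can be evaluated at the
top-k level: the fraction of foods whose true group appears among the k
highest-scored candidates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

from .food_table_io import NUTRIENT_ORDER, FoodTable
from .normalization import (
    DimensionlessTable,
    ScaleFactors,
    fit_dimensionless,
    project_matrix,
)
from .similarity import DegenerateVectorError

__all__ = [
    "GroupCentroid",
    "SKMModel",
    "RankedPrediction",
    "MLPModel",
    "StratificationError",
    "fit_skm",
    "predict_skm",
    "fit_mlp",
    "predict_mlp",
    "topk_accuracy",
    "stratified_cv",
    "CVResult",
    "OTHER_STRATUM",
]

#: Label under which groups too small to stratify are pooled during CV.
OTHER_STRATUM = "other"


class StratificationError(ValueError):
    """A group cannot be represented in every stratified split."""


@dataclass
class GroupCentroid:
    """One exchange group's representative unit direction."""

    group: str
    vector: np.ndarray  # unit-norm, dimensionless space
    support: int

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.support < 1:
            raise ValueError("centroid support must be >= 1")
        norm = np.linalg.norm(self.vector)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"centroid for {self.group!r} is not unit-norm ({norm})")


@dataclass
class SKMModel:
    """Supervised spherical-k-means model: one centroid per group."""

    centroids: list[GroupCentroid]
    scale: ScaleFactors

    def __post_init__(self) -> None:
        names = [c.group for c in self.centroids]
        if len(set(names)) != len(names):
            raise ValueError("centroid group names must be unique")
        if len(names) < 2:
            raise ValueError("need at least 2 centroids to classify")

    @property
    def groups(self) -> list[str]:
        return [c.group for c in self.centroids]

    def centroid_matrix(self) -> np.ndarray:
        return np.stack([c.vector for c in self.centroids])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "nutrients": list(NUTRIENT_ORDER),
                "centroids": [
                    {
                        "group": c.group,
                        "vector": c.vector.tolist(),
                        "support": c.support,
                    }
                    for c in self.centroids
                ],
                "scale": json.loads(self.scale.to_json()),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SKMModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text(encoding="utf-8")
        data = json.loads(text)
        centroids = [
            GroupCentroid(
                group=c["group"],
                vector=np.array(c["vector"], dtype=float),
                support=int(c["support"]),
            )
            for c in data["centroids"]
        ]
        scale = ScaleFactors(
            column_sums=np.array(data["scale"]["column_sums"], dtype=float),
            n=int(data["scale"]["n"]),
            degenerate=np.array(data["scale"]["degenerate"], dtype=bool),
        )
        return cls(centroids=centroids, scale=scale)


@dataclass
class RankedPrediction:
    """Full ranking of candidate groups for one food, best first.

    ``true_group_rank`` (1-based) is set when the true label is known; under
    score ties it is 1 + the number of groups with *strictly* greater score,
    so tied groups share the best rank deterministically.
    """

    ranking: list[tuple[str, float]]
    true_group_rank: int | None = None

    @property
    def top(self) -> str:
        return self.ranking[0][0]

    def topk(self, k: int) -> list[str]:
        return [g for g, _ in self.ranking[:k]]


def _ranked(
    groups: Sequence[str], scores: np.ndarray, true_group: str | None
) -> RankedPrediction:
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")  # ties keep model group order
    ranking = [(groups[i], float(scores[i])) for i in order]
    true_rank = None
    if true_group is not None:
        if true_group not in groups:
            raise ValueError(f"true group {true_group!r} unknown to the model")
        s_true = scores[list(groups).index(true_group)]
        true_rank = 1 + int(np.sum(scores > s_true))
    return RankedPrediction(ranking=ranking, true_group_rank=true_rank)


def fit_skm(dimtable: DimensionlessTable, labels: Sequence[str]) -> SKMModel:
    """Place one unit-norm centroid per group at the group's mean direction.

    Groups are kept in first-appearance order of the label sequence, which
    fixes the deterministic tie-break order of predictions.
    """
    labels = list(labels)
    if len(labels) != dimtable.n:
        raise ValueError("one label per table row required")
    if any(lab is None for lab in labels):
        raise ValueError("every row must be labeled to fit centroids")
    seen: dict[str, None] = {}
    for lab in labels:
        seen.setdefault(lab, None)
    centroids: list[GroupCentroid] = []
    lab_arr = np.array(labels)
    for group in seen:
        rows = dimtable.matrix[lab_arr == group]
        mean = rows.mean(axis=0)
        norm = np.linalg.norm(mean)
        if norm == 0:
            raise DegenerateVectorError(
                f"group {group!r} has an all-zero mean vector; no centroid direction"
            )
        centroids.append(
            GroupCentroid(group=group, vector=mean / norm, support=rows.shape[0])
        )
    return SKMModel(centroids=centroids, scale=dimtable.scale)


def predict_skm(
    model: SKMModel, vector: np.ndarray, true_group: str | None = None
) -> RankedPrediction:
    """Rank all groups by cosine similarity of a dimensionless vector to
    their centroids, descending; ties break by model centroid order."""
    v = np.asarray(vector, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise DegenerateVectorError("cannot classify a zero vector")
    scores = model.centroid_matrix() @ (v / norm)
    scores = np.clip(scores, 0.0, 1.0)
    return _ranked(model.groups, scores, true_group)


def predict_skm_matrix(
    model: SKMModel,
    matrix: np.ndarray,
    true_groups: Sequence[str] | None = None,
) -> list[RankedPrediction]:
    """Vectorized :func:`predict_skm` over the rows of a matrix."""
    x = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise DegenerateVectorError("cannot classify a zero vector")
    scores = np.clip((x / norms[:, None]) @ model.centroid_matrix().T, 0.0, 1.0)
    groups = model.groups
    out = []
    for i in range(x.shape[0]):
        tg = None if true_groups is None else true_groups[i]
        out.append(_ranked(groups, scores[i], tg))
    return out


# ---------------------------------------------------------------------------
# MLP classifier
# ---------------------------------------------------------------------------


def mlp_features(dimtable: DimensionlessTable) -> np.ndarray:
    """Stack the 9 dimensionless components with the magnitude feature."""
    return np.column_stack([dimtable.matrix, dimtable.magnitudes])


@dataclass
class MLPModel:
    """A trained feed-forward classifier over the 10-feature input.

    ``training_log`` records the cross-entropy loss on the training and
    internal validation split after every epoch; training is deterministic
    given ``seed``.
    """

    clf: MLPClassifier
    topology: tuple[int, ...]
    seed: int
    classes: list[str]
    training_log: dict[str, list[float]]
    validation_accuracy: float
    scale: ScaleFactors | None = None
    magnitude_source: str = "dimensionless"

    @property
    def final_loss(self) -> float:
        return self.training_log["train"][-1]


def fit_mlp(
    dimtable: DimensionlessTable,
    labels: Sequence[str],
    topology: tuple[int, int] = (32, 32),
    seed: int = 0,
    epochs: int = 300,
    split_fraction: float = 0.8,
    learning_rate_init: float = 0.01,
) -> MLPModel:
    """Train the MLP on 9 dimensionless components + magnitude.

    An internal stratified split holds out ``1 - split_fraction`` of the
    foods for validation; per-epoch train/validation cross-entropy is logged.
    Two hidden rectifier layers (widths from ``topology``) feed a softmax
    output over the groups.
    """
    labels = list(labels)
    if len(labels) != dimtable.n:
        raise ValueError("one label per table row required")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 distinct groups to train a classifier")
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    x = mlp_features(dimtable)
    y = np.array(labels)
    try:
        x_tr, x_va, y_tr, y_va = train_test_split(
            x,
            y,
            train_size=split_fraction,
            stratify=y,
            random_state=seed,
        )
    except ValueError as exc:
        raise StratificationError(
            f"stratified split failed (a group is too small): {exc}"
        ) from exc
    missing = set(classes) - set(y_tr)
    if missing:
        raise StratificationError(
            f"groups absent from the training split: {sorted(missing)}"
        )

    clf = MLPClassifier(
        hidden_layer_sizes=tuple(topology),
        activation="relu",
        solver="adam",
        learning_rate_init=learning_rate_init,
        random_state=seed,
        max_iter=1,
    )
    log: dict[str, list[float]] = {"train": [], "validation": []}
    class_arr = np.array(classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-step convergence warnings
        for _ in range(epochs):
            clf.partial_fit(x_tr, y_tr, classes=class_arr)
            log["train"].append(
                float(log_loss(y_tr, clf.predict_proba(x_tr), labels=class_arr))
            )
            log["validation"].append(
                float(log_loss(y_va, clf.predict_proba(x_va), labels=class_arr))
            )
    val_acc = float(np.mean(clf.predict(x_va) == y_va))
    return MLPModel(
        clf=clf,
        topology=tuple(topology),
        seed=seed,
        classes=list(clf.classes_),
        training_log=log,
        validation_accuracy=val_acc,
        scale=dimtable.scale,
    )


def predict_mlp(
    model: MLPModel, features: np.ndarray, true_group: str | None = None
) -> RankedPrediction:
    """Rank groups by the MLP's class probabilities for one 10-feature row."""
    f = np.asarray(features, dtype=float).reshape(1, -1)
    probs = model.clf.predict_proba(f)[0]
    return _ranked(model.classes, probs, true_group)


def predict_mlp_matrix(
    model: MLPModel,
    features: np.ndarray,
    true_groups: Sequence[str] | None = None,
) -> list[RankedPrediction]:
    probs = model.clf.predict_proba(np.asarray(features, dtype=float))
    out = []
    for i in range(probs.shape[0]):
        tg = None if true_groups is None else true_groups[i]
        out.append(_ranked(model.classes, probs[i], tg))
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def topk_accuracy(predictions: Sequence[RankedPrediction], k: int) -> float:
    """Fraction of predictions whose true group ranks within the first k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(predictions) == 0:
        raise ValueError("no predictions supplied")
    ranks = []
    for p in predictions:
        if p.true_group_rank is None:
            raise ValueError("every prediction must carry its true-group rank")
        ranks.append(p.true_group_rank)
    return float(np.mean(np.asarray(ranks) <= k))


@dataclass
class CVResult:
    """Per-fold accuracies of a stratified cross-validation run."""

    fold_accuracies: list[float]
    mean_accuracy: float
    fold_assignments: np.ndarray  # fold index per table row
    fold_scales: list[ScaleFactors] = field(default_factory=list)
    merged_groups: list[str] = field(default_factory=list)
    model_name: str = "skm"


def stratified_cv(
    table: FoodTable,
    model_spec: str | Callable[[], object] = "skm",
    n_splits: int = 5,
    seed: int = 0,
    mlp_kwargs: dict | None = None,
) -> CVResult:
    """Stratified k-fold evaluation with per-fold refitting.

    The dimensionless scale factors and the model are refitted on each
    fold's training portion only, so no statistic of a validation fold leaks
    into training.  Groups with fewer members than ``n_splits`` are merged
    into an ``"other"`` stratum (with a warning) so every fold can hold each
    stratum.  ``model_spec`` is ``"skm"``, ``"mlp"``, or a zero-argument
    factory returning a scikit-learn-style classifier (the adapter seam for
    off-the-shelf models such as random forests or gradient boosting), fitted
    on the 10-feature input.
    """
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    labels = table.labels
    if labels is None:
        raise ValueError("cross-validation requires a fully labeled table")
    y = np.array(labels)
    uniq, counts = np.unique(y, return_counts=True)
    small = [g for g, c in zip(uniq, counts) if c < n_splits]
    if small:
        warnings.warn(
            f"groups smaller than n_splits merged into {OTHER_STRATUM!r}: {small}",
            stacklevel=2,
        )
        y = np.where(np.isin(y, small), OTHER_STRATUM, y)

    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    assignments = np.full(table.n, -1, dtype=int)
    accuracies: list[float] = []
    scales: list[ScaleFactors] = []
    for fold, (tr_idx, va_idx) in enumerate(skf.split(table.vectors, y)):
        assignments[va_idx] = fold
        train_table = FoodTable(
            records=[table.records[i] for i in tr_idx],
            vectors=table.vectors[tr_idx],
        )
        dim_train = fit_dimensionless(train_table)
        scales.append(dim_train.scale)
        y_tr, y_va = y[tr_idx], y[va_idx]
        dim_va, mags_va = project_matrix(table.vectors[va_idx], dim_train.scale)
        if model_spec == "skm":
            model = fit_skm(dim_train, y_tr)
            preds = predict_skm_matrix(model, dim_va, y_va)
            acc = topk_accuracy(preds, 1)
        elif model_spec == "mlp":
            kw = dict(mlp_kwargs or {})
            kw.setdefault("seed", seed)
            mlp = fit_mlp(dim_train, y_tr, **kw)
            x_va = np.column_stack([dim_va, mags_va])
            preds = predict_mlp_matrix(mlp, x_va, y_va)
            acc = topk_accuracy(preds, 1)
        elif callable(model_spec):
            est = model_spec()
            x_tr = mlp_features(dim_train)
            est.fit(x_tr, y_tr)
            x_va = np.column_stack([dim_va, mags_va])
            acc = float(np.mean(np.asarray(est.predict(x_va)) == y_va))
        else:
            raise ValueError(f"unknown model_spec {model_spec!r}")
        accuracies.append(acc)
    return CVResult(
        fold_accuracies=accuracies,
        mean_accuracy=float(np.mean(accuracies)),
        fold_assignments=assignments,
        fold_scales=scales,
        merged_groups=list(small),
        model_name=model_spec if isinstance(model_spec, str) else "adapter",
    )
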