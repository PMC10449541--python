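"""Centroid placement, ranked prediction, top-k accuracy, cross-validation."""

import numpy as np
import pytest

from felkit import (
    FoodTable,
    fit_dimensionless,
    fit_mlp,
    fit_skm,
    predict_mlp,
    predict_skm,
    stratified_cv,
    topk_accuracy,
)
from felkit.classifiers import (
    OTHER_STRATUM,
    RankedPrediction,
    SKMModel,
    StratificationError,
    mlp_features,
    predict_skm_matrix,
)
from felkit.normalization import DimensionlessTable, ScaleFactors
from felkit.similarity import DegenerateVectorError
from felkit import default_group_profiles, generate_food_table


def dimtable(matrix):
    matrix = np.asarray(matrix, float)
    scale = ScaleFactors(column_sums=np.ones(9), n=matrix.shape[0])
    return DimensionlessTable(matrix=matrix, scale=scale,
                              magnitudes=np.linalg.norm(matrix, axis=1))


def vec(*head):
    v = np.zeros(9)
    v[: len(head)] = head
    return v


class TestFitSKM:
    def test_single_food_group_centroid_is_its_unit_vector(self):
        m = np.stack([vec(3, 4), vec(0, 1)])
        model = fit_skm(dimtable(m), ["a", "b"])
        np.testing.assert_allclose(model.centroids[0].vector, vec(0.6, 0.8))
        assert model.centroids[0].support == 1

    def test_parallel_foods_share_direction(self):
        m = np.stack([vec(1, 2), vec(2, 4), vec(0, 1)])
        model = fit_skm(dimtable(m), ["a", "a", "b"])
        np.testing.assert_allclose(
            model.centroids[0].vector, vec(1, 2) / np.sqrt(5), atol=1e-12
        )

    def test_two_orthogonal_foods_mean_direction(self):
        m = np.stack([vec(1), vec(0, 1), vec(0, 0, 1)])
        model = fit_skm(dimtable(m), ["g", "g", "h"])
        np.testing.assert_allclose(
            model.centroids[0].vector, vec(1 / np.sqrt(2), 1 / np.sqrt(2))
        )

    def test_zero_mean_group_rejected(self):
        m = np.stack([np.zeros(9), vec(1)])
        with pytest.raises(DegenerateVectorError):
            fit_skm(dimtable(m), ["z", "a"])

    def test_json_roundtrip(self, tmp_path):
        m = np.stack([vec(3, 4), vec(0, 1)])
        model = fit_skm(dimtable(m), ["a", "b"])
        path = tmp_path / "skm.json"
        model.to_json(path)
        back = SKMModel.from_json(path)
        assert back.groups == model.groups
        np.testing.assert_array_equal(
            back.centroid_matrix(), model.centroid_matrix()
        )


class TestPredictSKM:
    def test_vector_equal_to_centroid_scores_one(self):
        m = np.stack([vec(1), vec(0, 1)])
        model = fit_skm(dimtable(m), ["a", "b"])
        pred = predict_skm(model, vec(5))  # parallel to centroid a
        assert pred.top == "a"
        assert pred.ranking[0][1] == pytest.approx(1.0)

    def test_near_first_axis_prefers_first_group(self):
        m = np.stack([vec(1), vec(0, 1)])
        model = fit_skm(dimtable(m), ["a", "b"])
        assert predict_skm(model, vec(0.9, 0.1)).top == "a"

    def test_zero_vector_rejected(self):
        model = fit_skm(dimtable(np.stack([vec(1), vec(0, 1)])), ["a", "b"])
        with pytest.raises(DegenerateVectorError):
            predict_skm(model, np.zeros(9))

    def test_ranking_matches_brute_force_oracle(self, rng):
        """Full ranking equals an independent sort of cosine similarities."""
        from felkit.similarity import cosine_similarity

        m = rng.random((19, 9)) + 0.01
        labels = [f"g{i}" for i in range(19)]
        model = fit_skm(dimtable(m), labels)
        for _ in range(100):
            v = rng.random(9) + 1e-6
            pred = predict_skm(model, v)
            sims = np.array([
                cosine_similarity(v, c.vector) for c in model.centroids
            ])
            order = np.argsort(-sims, kind="stable")
            assert [g for g, _ in pred.ranking] == [labels[i] for i in order]

    def test_true_rank_with_ties_counts_strictly_greater(self):
        pred = RankedPrediction(ranking=[("a", 0.9), ("b", 0.9), ("c", 0.1)])
        from felkit.classifiers import _ranked
        r = _ranked(["a", "b", "c"], np.array([0.9, 0.9, 0.1]), "b")
        assert r.true_group_rank == 1  # tied with the best score


class TestTopkAccuracy:
    def rp(self, rank):
        return RankedPrediction(ranking=[("x", 1.0)], true_group_rank=rank)

    def test_all_first_place(self):
        assert topk_accuracy([self.rp(1)] * 5, 1) == 1.0

    def test_partial_counts(self):
        preds = [self.rp(1), self.rp(2), self.rp(4)]
        assert topk_accuracy(preds, 3) == pytest.approx(2 / 3)

    def test_monotone_and_exhaustive(self):
        preds = [self.rp(r) for r in (1, 3, 5, 7, 19)]
        accs = [topk_accuracy(preds, k) for k in range(1, 20)]
        assert all(a <= b for a, b in zip(accs, accs[1:]))
        assert accs[-1] == 1.0

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            topk_accuracy([self.rp(1)], 0)


@pytest.fixture(scope="module")
def two_group_table():
    profiles = [p for p in default_group_profiles()
                if p.group in ("Fruits", "Meat: Fish and poultry low-fat content")]
    return generate_food_table(profiles, n_per_group=100, noise_scale=0.1,
                               seed=11)


class TestFitMLP:
    def test_separable_groups_high_validation_accuracy(self, two_group_table):
        dim = fit_dimensionless(two_group_table)
        model = fit_mlp(dim, two_group_table.labels, seed=3, epochs=150)
        assert model.validation_accuracy >= 0.95

    def test_determinism_same_seed_same_loss(self, two_group_table):
        dim = fit_dimensionless(two_group_table)
        m1 = fit_mlp(dim, two_group_table.labels, seed=5, epochs=60)
        m2 = fit_mlp(dim, two_group_table.labels, seed=5, epochs=60)
        assert m1.final_loss == m2.final_loss
        assert m1.training_log == m2.training_log

    def test_training_log_finite_and_complete(self, two_group_table):
        dim = fit_dimensionless(two_group_table)
        model = fit_mlp(dim, two_group_table.labels, seed=5, epochs=40)
        assert len(model.training_log["train"]) == 40
        assert len(model.training_log["validation"]) == 40
        assert np.all(np.isfinite(model.training_log["train"]))
        # loss decreases overall (compare smoothed endpoints)
        tr = model.training_log["train"]
        assert np.mean(tr[-5:]) < np.mean(tr[:5])

    def test_single_class_rejected(self, two_group_table):
        dim = fit_dimensionless(two_group_table)
        with pytest.raises(ValueError, match="2 distinct groups"):
            fit_mlp(dim, ["same"] * two_group_table.n, seed=0)

    def test_singleton_group_is_stratification_error(self, two_group_table):
        dim = fit_dimensionless(two_group_table)
        labels = list(two_group_table.labels)
        labels[0] = "lonely"
        with pytest.raises(StratificationError):
            fit_mlp(dim, labels, seed=0)

    def test_predict_ranks_groups(self, two_group_table):
        dim = fit_dimensionless(two_group_table)
        model = fit_mlp(dim, two_group_table.labels, seed=3, epochs=150)
        x = mlp_features(dim)
        pred = predict_mlp(model, x[0], true_group=two_group_table.labels[0])
        assert set(g for g, _ in pred.ranking) == set(model.classes)
        assert pred.true_group_rank is not None


class TestStratifiedCV:
    def test_fold_sizes_19_groups_20_foods(self, synthetic_table):
        cv = stratified_cv(synthetic_table, "skm", n_splits=5, seed=0)
        labels = np.array(synthetic_table.labels)
        for fold in range(5):
            in_fold = labels[cv.fold_assignments == fold]
            _, counts = np.unique(in_fold, return_counts=True)
            assert np.all(counts == 4)

    def test_same_seed_same_folds(self, synthetic_table):
        cv1 = stratified_cv(synthetic_table, "skm", n_splits=5, seed=42)
        cv2 = stratified_cv(synthetic_table, "skm", n_splits=5, seed=42)
        np.testing.assert_array_equal(cv1.fold_assignments, cv2.fold_assignments)
        assert cv1.fold_accuracies == cv2.fold_accuracies

    def test_noiseless_data_perfect_accuracy(self):
        table = generate_food_table(default_group_profiles(), n_per_group=10,
                                    noise_scale=0.0, seed=0)
        cv = stratified_cv(table, "skm", n_splits=5, seed=0)
        assert cv.fold_accuracies == [1.0] * 5

    def test_scale_factors_refit_per_fold(self, synthetic_table):
        """Fold scale sums come from the training portion only (no leakage)."""
        cv = stratified_cv(synthetic_table, "skm", n_splits=5, seed=0)
        full = synthetic_table.vectors.sum(axis=0)
        for fold, scale in enumerate(cv.fold_scales):
            train_rows = synthetic_table.vectors[cv.fold_assignments != fold]
            np.testing.assert_allclose(scale.column_sums, train_rows.sum(axis=0))
            assert not np.allclose(scale.column_sums, full)

    def test_small_group_merged_into_other(self, synthetic_table):
        records = synthetic_table.records[:43]  # last group truncated to 3 < 5
        table = FoodTable(records=records, vectors=synthetic_table.vectors[:43])
        with pytest.warns(UserWarning, match=OTHER_STRATUM):
            cv = stratified_cv(table, "skm", n_splits=5, seed=0)
        assert cv.merged_groups

    def test_adapter_seam_runs_sklearn_estimator(self, synthetic_table):
        from sklearn.tree import DecisionTreeClassifier

        cv = stratified_cv(
            synthetic_table,
            lambda: DecisionTreeClassifier(random_state=0),
            n_splits=3,
            seed=0,
        )
        assert cv.model_name == "adapter"
        assert 0.0 <= cv.mean_accuracy <= 1.0
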