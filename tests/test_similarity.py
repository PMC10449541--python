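"""Cosine similarity, equivalence factor alpha, ranking, two-food blends."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from felkit import (
    FoodRecord,
    FoodTable,
    blend_factors,
    cosine_similarity,
    equivalence_factor,
    fit_dimensionless,
    rank_equivalents,
)
from felkit.similarity import DegenerateVectorError
from conftest import random_food_matrix


def vec(*head):
    v = np.zeros(9)
    v[: len(head)] = head
    return v


class TestCosineSimilarity:
    def test_identity_is_one(self):
        assert cosine_similarity(vec(2, 5, 1), vec(2, 5, 1)) == 1.0

    def test_orthogonal_is_zero(self):
        assert cosine_similarity(vec(1), vec(0, 1)) == 0.0

    def test_hand_computed_value(self):
        """(3,4) vs (4,3): cos = 24/25."""
        assert cosine_similarity(vec(3, 4), vec(4, 3)) == pytest.approx(0.96)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateVectorError):
            cosine_similarity(np.zeros(9), vec(1))

    @given(c=st.floats(1e-6, 1e6))
    def test_scale_invariance(self, c):
        a, b = vec(3, 4, 1), vec(4, 3, 2)
        assert cosine_similarity(a, c * b) == pytest.approx(cosine_similarity(a, b))

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(50):
            a = rng.random(9)
            b = rng.random(9)
            assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a))


class TestEquivalenceFactor:
    def test_identical_foods_alpha_one(self):
        assert equivalence_factor(vec(5, 2), vec(5, 2)) == pytest.approx(1.0)

    def test_doubled_food_alpha_two(self):
        b = vec(5, 2, 7)
        assert equivalence_factor(2 * b, b) == pytest.approx(2.0)

    def test_hand_computed_value(self):
        """<A,B>/|B|^2 = 24/25 for A=(3,4), B=(4,3)."""
        assert equivalence_factor(vec(3, 4), vec(4, 3)) == pytest.approx(0.96)

    @given(c=st.floats(1e-3, 1e3))
    def test_inverse_scaling_in_candidate(self, c):
        a, b = vec(3, 4, 1), vec(4, 3, 2)
        assert equivalence_factor(a, c * b) == pytest.approx(
            equivalence_factor(a, b) / c, rel=1e-9
        )

    def test_projection_optimality_grid_oracle(self, rng):
        """alpha beats every t on a fine grid around it (least-squares optimum)."""
        for _ in range(50):
            a = rng.random(9) * rng.integers(1, 100)
            b = rng.random(9) * rng.integers(1, 100)
            alpha = equivalence_factor(a, b)
            best = np.linalg.norm(a - alpha * b)
            ts = np.linspace(0, 4 * max(alpha, 1e-6), 401)
            residuals = np.linalg.norm(a[None, :] - ts[:, None] * b[None, :], axis=1)
            assert np.all(best <= residuals + 1e-12)

    def test_asymmetry_product_is_cos_squared(self, rng):
        for _ in range(20):
            a, b = rng.random(9) + 0.01, rng.random(9) + 0.01
            prod = equivalence_factor(a, b) * equivalence_factor(b, a)
            assert prod == pytest.approx(cosine_similarity(a, b) ** 2)
            assert prod <= 1.0 + 1e-12


class TestRankEquivalents:
    def test_exact_copy_ranks_first(self, small_table):
        dim = fit_dimensionless(small_table)
        target = FoodRecord(name="apple clone", group="Fruits", energy=52,
                            protein=0.3, total_lipids=0.2, saturated_fat=0.0,
                            cholesterol=0, carbohydrates=14, sugar=10,
                            fiber=2.4, sodium=1)
        results = rank_equivalents(target, small_table, dim.scale, k=4)
        assert results[0].candidate_name == "apple"
        assert results[0].similarity == pytest.approx(1.0)
        assert results[0].alpha == pytest.approx(1.0)
        assert results[0].grams == pytest.approx(100.0)

    def test_target_excluded_by_name(self, small_table):
        dim = fit_dimensionless(small_table)
        results = rank_equivalents(small_table.records[0], small_table,
                                   dim.scale, k=10)
        assert "apple" not in [r.candidate_name for r in results]
        assert len(results) == 3  # k larger than table returns all others

    def test_ordering_matches_brute_force(self, rng):
        from felkit.normalization import project_matrix
        from felkit.similarity import cosine_similarity as cs

        x = random_food_matrix(rng, 5, sparse_prob=0.0)
        recs = []
        for i, row in enumerate(x):
            e, p, u, s, ch, st_, su, f, na = row
            recs.append(FoodRecord(name=f"f{i}", energy=e, protein=p,
                                   total_lipids=u + s, saturated_fat=s,
                                   cholesterol=ch, carbohydrates=st_ + su + f,
                                   sugar=su, fiber=f, sodium=na, starch=st_))
        table = FoodTable.from_records(recs)
        dim = fit_dimensionless(table)
        results = rank_equivalents(recs[0], table, dim.scale, k=4)
        sims = {f"f{i}": cs(dim.matrix[0], dim.matrix[i]) for i in range(1, 5)}
        expected = sorted(sims, key=lambda nm: -sims[nm])
        assert [r.candidate_name for r in results] == expected

    def test_same_group_only_filters(self, small_table):
        dim = fit_dimensionless(small_table)
        results = rank_equivalents(small_table.records[0], small_table,
                                   dim.scale, k=5, same_group_only=True)
        assert [r.candidate_name for r in results] == ["banana"]

    def test_same_group_only_needs_labels(self, small_table):
        dim = fit_dimensionless(small_table)
        unlabeled = FoodTable(
            records=[FoodRecord(name="x", energy=1, protein=1, total_lipids=1,
                                saturated_fat=0, cholesterol=0, carbohydrates=1,
                                sugar=0, fiber=0, sodium=0)],
            vectors=small_table.vectors[:1],
        )
        with pytest.raises(ValueError, match="labeled"):
            rank_equivalents(small_table.records[0], unlabeled, dim.scale,
                             same_group_only=True)


class TestBlendFactors:
    def test_orthogonal_basis_exact(self):
        res = blend_factors(vec(2, 3), vec(1), vec(0, 1))
        assert res.alpha == pytest.approx(2.0)
        assert res.beta == pytest.approx(3.0)
        assert res.residual_norm == pytest.approx(0.0, abs=1e-12)

    def test_boundary_case_beta_zero(self):
        a, b = vec(1, 1), vec(0, 0, 1)
        res = blend_factors(1.5 * a, a, b)
        assert res.alpha == pytest.approx(1.5)
        assert res.beta == pytest.approx(0.0)

    def test_exact_recovery_random(self, rng):
        for _ in range(50):
            a = rng.random(9) + 0.05
            b = rng.random(9) + 0.05
            alpha, beta = rng.uniform(0.1, 3, size=2)
            res = blend_factors(alpha * a + beta * b, a, b)
            assert res.alpha == pytest.approx(alpha, abs=1e-6)
            assert res.beta == pytest.approx(beta, abs=1e-6)
            assert res.residual_norm < 1e-9

    def test_parallel_foods_rejected(self):
        a = vec(1, 2, 3)
        with pytest.raises(DegenerateVectorError, match="parallel"):
            blend_factors(vec(1, 1), a, 2.5 * a)

    def test_nonnegativity_enforced(self):
        # target pulls beta negative in the unconstrained solution
        a, b = vec(1, 0.9), vec(0.9, 1)
        c = 2 * a - 0.5 * b
        res = blend_factors(np.clip(c, 0, None), a, b)
        assert res.alpha >= 0 and res.beta >= 0

    def test_blend_never_worse_than_single_food(self, rng):
        from felkit import equivalence_factor

        for _ in range(30):
            a = rng.random(9) + 0.05
            b = rng.random(9) + 0.05
            c = rng.random(9) * 3
            res = blend_factors(c, a, b)
            single_a = np.linalg.norm(c - equivalence_factor(c, a) * a)
            single_b = np.linalg.norm(c - equivalence_factor(c, b) * b)
            assert res.residual_norm <= min(single_a, single_b) + 1e-9
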