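"""Rank-one decomposition: solvers, oracle equivalence, diagnostics."""

import numpy as np
import pytest

from remiseta import (
    DegenerateMatrixError,
    decompose_matrix,
    fit_correlation,
    group_vector_correlation,
    predict,
    rank_one_decompose,
)
from remiseta.rankone import UndefinedCorrelationError


def svd_oracle(grid):
    """Leading singular triple from the full dense decomposition."""
    u, s, vt = np.linalg.svd(grid)
    x, y = u[:, 0], vt[0]
    if x.sum() < 0:
        x, y = -x, -y
    return s[0], x, y


class TestExactInputs:
    def test_exact_rank_one_input_is_recovered(self):
        grid = 10 * np.outer([0.6, 0.8], [0.6, 0.8])
        model = rank_one_decompose(grid)
        assert model.c == pytest.approx(10, abs=1e-10)
        np.testing.assert_allclose(model.x, [0.6, 0.8], atol=1e-10)
        np.testing.assert_allclose(model.y, [0.6, 0.8], atol=1e-10)
        assert model.residual == pytest.approx(0, abs=1e-12)
        assert model.fit_correlation == pytest.approx(1.0)
        np.testing.assert_allclose(predict(model), grid, atol=1e-10)

    def test_predict_unit_model(self):
        grid = np.zeros((2, 5))
        grid[0, 0] = 1.0
        model = rank_one_decompose(grid)
        np.testing.assert_allclose(predict(model), grid, atol=1e-12)

    def test_all_zero_grid_is_degenerate(self):
        with pytest.raises(DegenerateMatrixError):
            rank_one_decompose(np.zeros((3, 4)))


class TestOracleEquivalence:
    def test_small_random_grid_matches_oracle(self):
        rng = np.random.default_rng(42)
        grid = rng.integers(0, 20, size=(5, 4)).astype(float)
        model = rank_one_decompose(grid)
        c, x, y = svd_oracle(grid)
        assert model.c == pytest.approx(c, abs=1e-8)
        np.testing.assert_allclose(np.abs(model.x), np.abs(x), atol=1e-8)
        np.testing.assert_allclose(np.abs(model.y), np.abs(y), atol=1e-8)

    @pytest.mark.parametrize("method", ["svd", "power"])
    def test_200_random_grids_match_oracle(self, method):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            m = int(rng.integers(3, 41))
            n = int(rng.integers(3, 21))
            grid = rng.integers(0, 25, size=(m, n)).astype(float)
            if not grid.any():
                continue
            model = rank_one_decompose(grid, method=method)
            c, x, y = svd_oracle(grid)
            assert model.c == pytest.approx(c, abs=1e-8)
            np.testing.assert_allclose(np.abs(model.x), np.abs(x), atol=1e-8)
            np.testing.assert_allclose(np.abs(model.y), np.abs(y), atol=1e-8)

    def test_power_and_svd_agree(self):
        rng = np.random.default_rng(7)
        grid = rng.integers(0, 30, size=(12, 20)).astype(float)
        m_svd = rank_one_decompose(grid, method="svd")
        m_pow = rank_one_decompose(grid, method="power")
        assert m_pow.c == pytest.approx(m_svd.c, abs=1e-8)
        np.testing.assert_allclose(m_pow.x, m_svd.x, atol=1e-8)
        np.testing.assert_allclose(m_pow.y, m_svd.y, atol=1e-8)

    def test_als_with_full_mask_agrees_with_svd(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            grid = rng.integers(0, 25, size=(9, 7)).astype(float) + 1
            m_svd = rank_one_decompose(grid, method="svd")
            m_als = rank_one_decompose(grid, method="als_masked")
            assert m_als.c == pytest.approx(m_svd.c, abs=1e-6)
            np.testing.assert_allclose(m_als.x, m_svd.x, atol=1e-6)
            np.testing.assert_allclose(m_als.y, m_svd.y, atol=1e-6)

    def test_als_ignores_masked_cells(self):
        # corrupt one cell, mask it out: fit must match the clean grid's
        rng = np.random.default_rng(9)
        clean = 50 * np.outer(
            np.abs(rng.standard_normal(8)) + 0.5, np.abs(rng.standard_normal(6)) + 0.5
        )
        grid = clean.copy()
        grid[3, 2] = 1e4
        mask = np.ones(grid.shape, bool)
        mask[3, 2] = False
        model = rank_one_decompose(grid, mask, method="als_masked")
        ref = rank_one_decompose(clean, method="svd")
        assert model.c == pytest.approx(ref.c, rel=1e-6)
        np.testing.assert_allclose(model.x, ref.x, atol=1e-6)


class TestNormalizationInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_unit_norm_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.integers(0, 15, size=(10, 20)).astype(float)
        model = rank_one_decompose(grid)
        assert np.sum(model.x**2) == pytest.approx(1, abs=1e-10)
        assert np.sum(model.y**2) == pytest.approx(1, abs=1e-10)
        assert model.c > 0
        assert (model.x >= -1e-12).all() and (model.y >= -1e-12).all()


class TestFixtureModels:
    def test_fit_correlations_round_to_printed_values(self, model_a, model_f):
        assert round(model_a.fit_correlation, 2) == 0.98
        assert round(model_f.fit_correlation, 2) == 0.97

    def test_group_vector_correlation(self, model_a, model_f):
        assert round(group_vector_correlation(model_a, model_f), 2) == 0.93

    def test_scale_coefficient_tracks_age(self, model_a, model_f):
        # specimen A has more somites (older); its scale must be larger
        assert model_a.c > model_f.c

    def test_residual_optimality_under_perturbation(self, matrix_a, model_a):
        from remiseta import to_grid

        grid, _ = to_grid(matrix_a, "zero")
        rng = np.random.default_rng(77)
        for _ in range(100):
            x = model_a.x + 0.01 * rng.standard_normal(model_a.x.shape)
            y = model_a.y + 0.01 * rng.standard_normal(model_a.y.shape)
            x /= np.linalg.norm(x)
            y /= np.linalg.norm(y)
            c = float(x @ grid @ y)  # optimal scale for fixed directions
            resid = float(np.sum((grid - c * np.outer(x, y)) ** 2))
            assert resid >= model_a.residual - 1e-9

    def test_self_correlation_is_one(self, model_a):
        assert group_vector_correlation(model_a, model_a) == pytest.approx(1.0)

    def test_correlation_invariant_to_positive_affine_transform(self, model_a, model_f):
        shifted = type(model_f)(
            c=model_f.c,
            x=model_f.x,
            y=2.5 * model_a.y + 0.1,
            residual=0.0,
            fit_correlation=1.0,
            method="svd",
        )
        assert group_vector_correlation(model_a, shifted) == pytest.approx(1.0)


class TestCorrelationErrors:
    def test_constant_prediction_is_undefined(self):
        grid = np.ones((3, 3))
        model = rank_one_decompose(grid)
        with pytest.raises(UndefinedCorrelationError):
            fit_correlation(grid, model)

    def test_constant_group_vectors_are_undefined(self, model_a):
        flat = type(model_a)(
            c=1.0,
            x=model_a.x,
            y=np.full(20, np.sqrt(1 / 20)),
            residual=0.0,
            fit_correlation=1.0,
            method="svd",
        )
        with pytest.raises(UndefinedCorrelationError):
            group_vector_correlation(model_a, flat)


def test_masked_policy_reported_alongside_default(matrix_f):
    """Both missing-data policies run on the posterior-tail specimen."""
    dense = decompose_matrix(matrix_f, "zero")
    masked = decompose_matrix(matrix_f, "mask")
    assert masked.method == "als_masked"
    # masked fit ignores the structurally absent cells, so the two
    # policies give close but not identical diagnostics
    assert abs(dense.fit_correlation - masked.fit_correlation) < 0.05
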