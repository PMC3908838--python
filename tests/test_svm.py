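import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog
from scipy.stats import spearmanr

from fcranker.svm import (
    KernelConfig,
    discriminant,
    fit_fuzzy_lp_svm,
    kernel_matrix,
    rbf_kernel,
    sample_columns,
)


def oracle_lp_objective(K, y, y_cols, theta, c):
    """Independent LP assembly with variable order [r, b, xi, alpha],
    solved with the interior-point method."""
    l, lp = K.shape
    cost = np.concatenate([[-1.0, 0.0], c * theta, np.zeros(lp)])
    # y_i(sum_j alpha_j y'_j K_ij + b) - r + xi_i >= 0  ->  A_ub x <= 0
    A = np.hstack([
        np.ones((l, 1)),
        -y[:, None],
        -np.eye(l),
        -(y[:, None] * K * y_cols[None, :]),
    ])
    bounds = [(0, None), (None, None)] + [(0, None)] * l + [(-1, 1)] * lp
    res = linprog(cost, A_ub=A, b_ub=np.zeros(l), bounds=bounds, method="highs-ipm")
    assert res.success
    return res.fun


def random_instance(rng, n=None, q=None, reduced=False, fuzzy=True):
    n = n or int(rng.integers(4, 21))
    q = q or int(rng.integers(1, 5))
    X = rng.normal(size=(n, q))
    y = rng.choice([-1.0, 1.0], size=n)
    if not np.any(y > 0):
        y[0] = 1.0
    if not np.any(y < 0):
        y[0] = -1.0
    theta = np.where(y < 0, 1.0, rng.uniform(0, 1, n)) if fuzzy else np.ones(n)
    # boundedness: raising r (with b tilted toward the heavy class) costs
    # 2c * sum(theta) of the lighter class per unit, so each class needs
    # theta-mass above 1/(2c); decoys sit at 1, targets may need a bump
    cfg = KernelConfig(sigma=float(rng.uniform(0.5, 3.0)), c=float(rng.uniform(1.0, 2.0)))
    pos = np.flatnonzero(y > 0)
    need = 1.2 / (2.0 * cfg.c)
    if theta[pos].sum() < need:
        theta[pos[0]] = min(1.0, need)
    cols = np.arange(n)
    if reduced:
        cols = sample_columns(cols, 0.5, int(rng.integers(0, 1000)))
    K = kernel_matrix(X, np.arange(n), cols, cfg)
    return K, y, y[cols], theta, cfg, cols, X


class TestKernel:
    def test_zero_distance_gives_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rbf_kernel(x, x, sigma=2.0) == 1.0

    def test_scalar_value(self):
        # ||x1 - x2|| = 2, sigma = 2 -> exp(-4 / 8)
        assert rbf_kernel(np.array([0.0]), np.array([2.0]), 2.0) == pytest.approx(
            np.exp(-0.5), abs=1e-9
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 5))
        k = rbf_kernel(a, b, 1.5)
        assert k == pytest.approx(rbf_kernel(b, a, 1.5))
        assert 0 < k <= 1

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            rbf_kernel(np.zeros(2), np.zeros(3), 1.0)

    def test_matrix_shape_symmetry_diagonal(self, rng):
        X = rng.normal(size=(30, 3))
        cfg = KernelConfig()
        full = kernel_matrix(X, np.arange(30), np.arange(30), cfg)
        assert full.shape == (30, 30)
        np.testing.assert_allclose(full, full.T)
        np.testing.assert_allclose(np.diag(full), 1.0)
        assert np.all((full > 0) & (full <= 1))
        block = kernel_matrix(X, np.arange(30), np.arange(20), cfg)
        assert block.shape == (30, 20)


class TestSampleColumns:
    def test_fraction_one_is_identity(self):
        omega = np.arange(37)
        assert sample_columns(omega, 1.0, 3) is omega

    def test_count_and_distinctness(self):
        cols = sample_columns(np.arange(100), 0.2, 7)
        assert len(cols) == 20
        assert len(np.unique(cols)) == 20

    def test_deterministic_given_seed(self):
        a = sample_columns(np.arange(50), 0.3, 11)
        b = sample_columns(np.arange(50), 0.3, 11)
        np.testing.assert_array_equal(a, b)


class TestLPSVM:
    def two_point_model(self):
        X = np.array([[0.0], [2.0]])
        y = np.array([1.0, -1.0])
        cfg = KernelConfig(sigma=2.0, c=1.0)
        K = kernel_matrix(X, np.arange(2), np.arange(2), cfg)
        return fit_fuzzy_lp_svm(K, y, y, np.ones(2), cfg), K, y

    def test_two_point_closed_form(self):
        model, _, _ = self.two_point_model()
        r_expected = 1.0 - np.exp(-0.5)
        assert model.r == pytest.approx(r_expected, abs=1e-6)
        assert model.objective == pytest.approx(-r_expected, abs=1e-6)
        assert model.b == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(model.xi, 0.0, atol=1e-6)

    def test_two_point_discriminant(self):
        model, K, y = self.two_point_model()
        f = discriminant(model, K, y)
        np.testing.assert_allclose(f, [1 - np.exp(-0.5), -(1 - np.exp(-0.5))], atol=1e-6)

    def test_objective_never_positive(self, rng):
        for _ in range(10):
            K, y, y_cols, theta, cfg, cols, _ = random_instance(rng)
            model = fit_fuzzy_lp_svm(K, y, y_cols, theta, cfg, cols)
            assert model.objective <= 1e-9

    def test_matches_independent_oracle(self, rng):
        for _ in range(15):
            K, y, y_cols, theta, cfg, cols, _ = random_instance(rng)
            model = fit_fuzzy_lp_svm(K, y, y_cols, theta, cfg, cols)
            assert model.objective == pytest.approx(
                oracle_lp_objective(K, y, y_cols, theta, cfg.c), abs=1e-6
            )

    def test_constraints_and_bounds_hold(self, rng):
        K, y, y_cols, theta, cfg, cols, _ = random_instance(rng, n=15)
        model = fit_fuzzy_lp_svm(K, y, y_cols, theta, cfg, cols)
        f = discriminant(model, K, y_cols)
        assert np.all(y * f >= model.r - model.xi - 1e-6)
        assert np.all(np.abs(model.alpha) <= 1 + 1e-7)
        assert np.all(model.xi >= -1e-9)
        assert model.r >= -1e-9

    def test_zero_weight_relaxes_slack_cost(self, rng):
        K, y, y_cols, theta, cfg, cols, _ = random_instance(rng, n=12, fuzzy=False)
        base = fit_fuzzy_lp_svm(K, y, y_cols, theta, cfg, cols)
        theta2 = theta.copy()
        theta2[np.flatnonzero(y > 0)[0]] = 0.0
        relaxed = fit_fuzzy_lp_svm(K, y, y_cols, theta2, cfg, cols)
        assert relaxed.objective <= base.objective + 1e-9

    def test_theta_c_rescaling_invariance(self, rng):
        K, y, y_cols, theta, cfg, cols, _ = random_instance(rng, n=12)
        base = fit_fuzzy_lp_svm(K, y, y_cols, theta, cfg, cols)
        kappa = 2.5
        cfg2 = KernelConfig(sigma=cfg.sigma, c=cfg.c / kappa)
        scaled = fit_fuzzy_lp_svm(K, y, y_cols, kappa * theta, cfg2, cols)
        # c * sum(theta xi) is unchanged, so the optimal value agrees
        assert scaled.objective == pytest.approx(base.objective, abs=1e-8)

    def test_reduced_columns_full_fraction_equals_full(self, rng):
        K, y, y_cols, theta, cfg, cols, X = random_instance(rng, n=15)
        cols_full = sample_columns(np.arange(15), 1.0, 0)
        np.testing.assert_array_equal(cols_full, np.arange(15))
        K_full = kernel_matrix(X, np.arange(15), cols_full, cfg)
        a = fit_fuzzy_lp_svm(K_full, y, y[cols_full], theta, cfg, cols_full)
        b = fit_fuzzy_lp_svm(K_full, y, y, theta, cfg)
        assert a.objective == pytest.approx(b.objective, abs=1e-12)

    def test_reduced_columns_preserve_ranking(self):
        # well-separated two-cluster data: half the expansion columns
        # must essentially reproduce the full discriminant ordering
        rng = np.random.default_rng(5)
        n = 60
        X = np.vstack([rng.normal(3, 1, (n // 2, 2)), rng.normal(-3, 1, (n // 2, 2))])
        y = np.r_[np.ones(n // 2), -np.ones(n // 2)]
        theta = np.ones(n)
        cfg = KernelConfig()
        omega = np.arange(n)
        K_full = kernel_matrix(X, omega, omega, cfg)
        full = fit_fuzzy_lp_svm(K_full, y, y, theta, cfg)
        cols = sample_columns(omega, 0.5, 42)
        K_red = kernel_matrix(X, omega, cols, cfg)
        red = fit_fuzzy_lp_svm(K_red, y, y[cols], theta, cfg, cols)
        rho = spearmanr(
            discriminant(full, K_full, y), discriminant(red, K_red, y[cols])
        ).statistic
        assert rho >= 0.9

    def test_misaligned_eval_block_rejected(self):
        model, K, y = self.two_point_model()
        with pytest.raises(ValueError, match="columns"):
            discriminant(model, K[:, :1], y[:1])
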