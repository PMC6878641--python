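"""Statistical core: Moran's I, OLS, ML spatial lag, spatial probit, and the
forward simulator, each checked against an independent oracle."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import spatialboot as sb

from conftest import random_weights


# ---------------------------------------------------------------- oracles
def moran_brute_force(values, Wd):
    """Independent double-sum evaluation of Moran's I."""
    n = len(values)
    z = np.asarray(values, float) - np.mean(values)
    s0 = 0.0
    num = 0.0
    for i in range(n):
        for j in range(n):
            s0 += Wd[i, j]
            num += Wd[i, j] * z[i] * z[j]
    return (n / s0) * num / sum(zi * zi for zi in z)


def concentrated_loglik_grid(y, X, Wd, omega, rhos):
    """Brute-force profile log-likelihood of the spatial lag model on a rho
    grid, written independently of the fitting code."""
    n = len(y)
    M = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    Wy = Wd @ y
    lls = np.empty(len(rhos))
    for k, r in enumerate(rhos):
        u = M @ (y - r * Wy)
        sigma2 = u @ u / n
        lls[k] = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) \
            + np.sum(np.log(np.abs(1.0 - r * omega)))
    return lls


# ---------------------------------------------------------------- Moran's I
class TestMoransI:
    def test_constant_vector_rejected(self):
        W = random_weights(np.random.default_rng(0), 6)
        with pytest.raises(ValueError, match="zero variance"):
            sb.morans_i(np.ones(6), W)

    def test_length_mismatch_rejected(self):
        W = random_weights(np.random.default_rng(0), 6)
        with pytest.raises(ValueError, match="length"):
            sb.morans_i(np.arange(5.0), W)

    def test_expected_value_closed_form(self):
        W = random_weights(np.random.default_rng(1), 10)
        res = sb.morans_i(np.random.default_rng(2).normal(size=10), W)
        assert res.expected == -1.0 / 9.0
        # the survey scale from the motivating design: 850 clusters
        assert -1.0 / (850 - 1) == pytest.approx(-0.0011779, abs=5e-8)

    def test_line_example_matches_brute_force(self, line_coords):
        W = sb.row_normalize(sb.build_inverse_distance_matrix(line_coords))
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        res = sb.morans_i(vals, W)
        assert res.I == pytest.approx(moran_brute_force(vals, W.toarray()),
                                      abs=1e-12)

    @given(st.integers(3, 12), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_on_random_instances(self, n, seed):
        rng = np.random.default_rng(seed)
        W = random_weights(rng, n, normalized=bool(seed % 2))
        vals = rng.normal(size=n)
        res = sb.morans_i(vals, W)
        assert res.I == pytest.approx(moran_brute_force(vals, W.toarray()),
                                      abs=1e-12)

    def test_permutation_p_bounds_and_determinism(self):
        rng = np.random.default_rng(3)
        W = random_weights(rng, 15)
        vals = rng.normal(size=15)
        r1 = sb.morans_i(vals, W, inference="permutation", n_perm=99, seed=42)
        r2 = sb.morans_i(vals, W, inference="permutation", n_perm=99, seed=42)
        assert r1.p_value == r2.p_value
        assert 1.0 / 100 <= r1.p_value <= 1.0

    def test_permutation_p_uniform_under_null(self):
        """Under i.i.d. values the permutation p-value is uniform (KS at 1%)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(4)
        W = random_weights(rng, 20)
        ps = []
        for k in range(500):
            vals = rng.normal(size=20)
            ps.append(sb.morans_i(vals, W, inference="permutation",
                                  n_perm=199, seed=k).p_value)
        assert kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------- OLS
class TestOLS:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        beta = np.array([2.0, -1.5])
        fit = sb.fit_ols(X @ beta, X, names=["Intercept", "x"])
        assert fit.params.to_numpy() == pytest.approx(beta, abs=1e-10)

    def test_intercept_only_is_mean(self):
        y = np.array([1.0, 2.0, 4.0, 9.0])
        fit = sb.fit_ols(y, np.ones((4, 1)), names=["Intercept"])
        assert fit.params["Intercept"] == pytest.approx(np.mean(y))

    def test_fixed_table_matches_normal_equations(self):
        # n=10 toy table; oracle solves X'X b = X'y directly
        X = np.column_stack([np.ones(10), np.arange(10.0),
                             np.array([3, 1, 4, 1, 5, 9, 2, 6, 5, 3.0])])
        y = np.array([2.1, 2.9, 4.2, 3.8, 6.1, 8.9, 5.0, 8.2, 7.9, 7.1])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        fit = sb.fit_ols(y, X)
        assert fit.params.to_numpy() == pytest.approx(oracle, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
        with pytest.raises(ValueError, match="collinear"):
            sb.fit_ols(np.random.default_rng(6).normal(size=20), X,
                       names=["Intercept", "a", "a_times_two"])


# ---------------------------------------------------------------- spatial lag
class TestSpatialLagML:
    def test_requires_normalized_w(self):
        rng = np.random.default_rng(7)
        W = random_weights(rng, 10, normalized=False)
        with pytest.raises(ValueError, match="row-normalized"):
            sb.SpatialLag(rng.normal(size=10), np.ones((10, 1)), W)

    def test_rho_zero_noiseless_reduces_to_ols(self):
        rng = np.random.default_rng(8)
        n = 40
        W = random_weights(rng, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([1.0, 0.7])
        y = sb.simulate_spatial_lag(W, X, 0.0, beta, 0.0, seed=0)
        fit = sb.SpatialLag(y, X, W).fit()
        assert abs(fit.rho) < 1e-6
        assert fit.beta.to_numpy() == pytest.approx(beta, abs=1e-6)

    def test_toy_instance_matches_grid_oracle(self):
        rng = np.random.default_rng(9)
        n = 6
        pts = rng.uniform(0, 10, size=(n, 2))
        coords = sb.CoordinateSet(np.arange(n), pts[:, 0], pts[:, 1])
        W = sb.row_normalize(sb.build_inverse_distance_matrix(coords, alpha=3.0))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = sb.simulate_spatial_lag(W, X, 0.5, np.array([0.5, 1.0]), 0.2, seed=1)
        fit = sb.SpatialLag(y, X, W).fit()
        rhos = np.arange(-0.99, 0.99, 1e-4)
        lls = concentrated_loglik_grid(y, X, W.toarray(), W.eigenvalues(), rhos)
        k = int(np.argmax(lls))
        assert 0 < k < len(rhos) - 1  # interior optimum, fair comparison
        assert fit.rho == pytest.approx(rhos[k], abs=2e-4)
        # and the ML optimum dominates every grid point probed by the oracle
        m = sb.SpatialLag(y, X, W)
        assert m.concentrated_loglike(fit.rho) >= lls.max() - 1e-9

    def test_ci_brackets_estimate_and_rho_in_interval(self):
        rng = np.random.default_rng(10)
        n = 50
        W = random_weights(rng, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = sb.simulate_spatial_lag(W, X, 0.3, np.array([0.5, 1.0]), 1.0, seed=2)
        fit = sb.SpatialLag(y, X, W).fit()
        ci = fit.conf_int()
        assert (ci["ci_low"] <= fit.params).all()
        assert (fit.params <= ci["ci_high"]).all()
        lo, hi = fit.rho_interval
        assert lo < fit.rho < hi

    def test_loglik_reported_at_optimum(self):
        rng = np.random.default_rng(11)
        n = 30
        W = random_weights(rng, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = sb.simulate_spatial_lag(W, X, 0.2, np.array([0.0, 1.0]), 1.0, seed=3)
        m = sb.SpatialLag(y, X, W)
        fit = m.fit()
        assert fit.llf == pytest.approx(m.concentrated_loglike(fit.rho), abs=1e-8)


# ---------------------------------------------------------------- simulator
class TestSimulateSpatialLag:
    def test_rho_zero_is_linear_model(self):
        rng = np.random.default_rng(12)
        n = 20
        W = random_weights(rng, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([1.0, 2.0])
        y = sb.simulate_spatial_lag(W, X, 0.0, beta, 0.0)
        assert y == pytest.approx(X @ beta, abs=1e-12)

    def test_all_zero_case(self):
        W = random_weights(np.random.default_rng(13), 5)
        y = sb.simulate_spatial_lag(W, np.ones((5, 1)), 0.0, np.zeros(1), 0.0)
        assert np.all(y == 0.0)

    def test_fixed_point_identity(self):
        rng = np.random.default_rng(14)
        n = 25
        W = random_weights(rng, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([0.5, -1.0])
        draw_rng = np.random.default_rng(999)
        y = sb.simulate_spatial_lag(W, X, 0.6, beta, 1.0, rng=draw_rng)
        # reconstruct the identical noise draw and check y = rho W y + X b + e
        eps = np.random.default_rng(999).normal(0.0, 1.0, size=n)
        resid = y - 0.6 * (W.toarray() @ y) - X @ beta - eps
        assert np.max(np.abs(resid)) < 1e-10

    def test_probit_link_thresholds(self):
        rng = np.random.default_rng(15)
        n = 30
        W = random_weights(rng, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = sb.simulate_spatial_lag(W, X, 0.2, np.array([0.0, 1.0]), 1.0,
                                    link="probit", seed=4)
        assert set(np.unique(y)) <= {0.0, 1.0}


# ---------------------------------------------------------------- spatial probit
class TestSpatialProbit:
    def test_single_class_outcome_rejected(self):
        rng = np.random.default_rng(16)
        W = random_weights(rng, 10)
        with pytest.raises(ValueError, match="no variation"):
            sb.SpatialProbit(np.ones(10), np.ones((10, 1)), W)

    def test_seeded_draws_bit_identical(self):
        rng = np.random.default_rng(17)
        n = 30
        W = random_weights(rng, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = sb.simulate_spatial_lag(W, X, 0.3, np.array([0.0, 1.0]), 1.0,
                                    link="probit", seed=5)
        f1 = sb.SpatialProbit(y, X, W).fit(n_draws=40, burn_in=10, seed=7)
        f2 = sb.SpatialProbit(y, X, W).fit(n_draws=40, burn_in=10, seed=7)
        assert f1.draws.equals(f2.draws)

    def test_rho_pinned_reduction_matches_ml_probit(self):
        rng = np.random.default_rng(18)
        n = 200
        W = random_weights(rng, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (X @ np.array([-0.2, 1.0]) + rng.normal(size=n) > 0).astype(float)
        fit = sb.SpatialProbit(y, X, W, names=["Intercept", "x"]).fit(
            n_draws=800, burn_in=200, seed=8, rho_fixed=0.0)
        ml = sm.Probit(y, X).fit(disp=0)
        for j, name in enumerate(["Intercept", "x"]):
            assert abs(fit.params[name] - ml.params[j]) < 3 * fit.bse[name]

    def test_posterior_interval_brackets_mean(self):
        rng = np.random.default_rng(19)
        n = 60
        W = random_weights(rng, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = sb.simulate_spatial_lag(W, X, 0.3, np.array([0.0, 1.0]), 1.0,
                                    link="probit", seed=9)
        fit = sb.SpatialProbit(y, X, W).fit(n_draws=200, burn_in=50, seed=10)
        ci = fit.conf_int()
        assert (ci["ci_low"] <= fit.params).all()
        assert (fit.params <= ci["ci_high"]).all()


# ---------------------------------------------------------------- serialization
def test_fit_serializes_to_json(tmp_path):
    rng = np.random.default_rng(20)
    n = 30
    W = random_weights(rng, n)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = sb.simulate_spatial_lag(W, X, 0.2, np.array([0.5, 1.0]), 1.0, seed=11)
    fit = sb.SpatialLag(y, X, W, names=["Intercept", "x"]).fit()
    import json

    d = json.loads(fit.to_json(tmp_path / "fit.json"))
    assert d["method"] == "ml"
    assert d["rho"] == pytest.approx(fit.rho)
    assert set(d["coefficients"]) == {"rho", "Intercept", "x"}
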