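"""Tests of the comparison learners: tree, elastic net/Lasso, max-corr."""

import numpy as np
import pytest
from scipy import optimize

from drugsense.learners import (
    elastic_net_fit,
    fold_indices,
    lasso_sparsity_sweep,
    max_corr_fit,
    select_alpha_lambda,
    tree_fit,
)


class TestRegressionTree:
    def test_perfect_binary_split(self, rng):
        x = np.array([0] * 8 + [1] * 8)
        y = np.where(x == 0, 0.2, 0.8).astype(float)
        X = np.c_[x, rng.standard_normal(16)]
        m = tree_fit(X, y, min_bucket=5, rng=np.random.default_rng(0))
        assert m.root_feature == 0
        assert m.estimator.get_depth() == 1
        assert np.allclose(m.predict(X), y)  # training R^2 = 1

    def test_constant_response_gives_stump(self):
        X = np.arange(20, dtype=float)[:, None]
        y = np.full(20, 3.5)
        m = tree_fit(X, y, rng=np.random.default_rng(0))
        assert m.root_feature is None
        assert np.allclose(m.predict(X), 3.5)

    def test_xor_recovered_at_depth_two(self):
        # balanced XOR of two binary features, >= 5 lines per cell; the
        # exhaustive tree over the 4 cells predicts the cell means exactly
        x1 = np.array([0, 0, 1, 1] * 6)
        x2 = np.array([0, 1, 0, 1] * 6)
        y = (x1 ^ x2).astype(float)
        X = np.c_[x1, x2]
        m = tree_fit(X, y, min_bucket=5, rng=np.random.default_rng(0))
        assert m.estimator.get_depth() == 2
        used = set(m.estimator.tree_.feature[m.estimator.tree_.feature >= 0])
        assert used == {0, 1}
        # brute-force oracle: mean of y within each (x1, x2) cell
        oracle = np.array([y[(x1 == a) & (x2 == b)].mean() for a, b in zip(x1, x2)])
        assert np.allclose(m.predict(X), oracle)

    def test_invariant_to_monotone_feature_transform(self, rng):
        # threshold splits depend only on the feature ordering, so a
        # strictly monotone transform leaves predictions unchanged
        x = rng.uniform(-2, 2, 40)
        y = np.where(x < -1, 0.0, np.where(x < 0.5, 1.0, 2.0))
        y = y + 0.05 * rng.standard_normal(40)
        m1 = tree_fit(x[:, None], y, rng=np.random.default_rng(1))
        m2 = tree_fit((x**3)[:, None], y, rng=np.random.default_rng(1))
        assert np.allclose(m1.predict(x[:, None]), m2.predict((x**3)[:, None]))

    def test_weakest_link_pruning_matches_sklearn_refits(self, rng):
        # the fast pruning evaluation must agree with refitting sklearn at
        # every cost-complexity level of the pruning sequence
        from sklearn.tree import DecisionTreeRegressor

        from drugsense.learners import _collapse_alphas, _pruned_predictions

        for trial in range(10):
            X = (rng.uniform(size=(35, 8)) < 0.4).astype(float)
            y = rng.standard_normal(35)
            full = DecisionTreeRegressor(min_samples_leaf=5, random_state=0).fit(X, y)
            alphas = np.unique(
                np.clip(full.cost_complexity_pruning_path(X, y).ccp_alphas, 0, None)
            )
            Xte = (rng.uniform(size=(10, 8)) < 0.4).astype(float)
            mine = _pruned_predictions(full, _collapse_alphas(full), Xte, alphas)
            for j, a in enumerate(alphas):
                ref = DecisionTreeRegressor(
                    min_samples_leaf=5, random_state=0, ccp_alpha=a * (1 + 1e-9) + 1e-15
                ).fit(X, y).predict(Xte)
                assert np.allclose(mine[:, j], ref)

    def test_min_bucket_respected(self, rng):
        X = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        m = tree_fit(X, y, min_bucket=5, rng=np.random.default_rng(0))
        tree = m.estimator.tree_
        leaf_sizes = tree.n_node_samples[tree.children_left == -1]
        assert (leaf_sizes >= 5).all()


class TestElasticNet:
    def test_heavy_penalty_shrinks_to_mean(self, rng):
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30) + 2.0
        m = elastic_net_fit(X, y, alpha=0.5, lam=1e6)
        assert np.allclose(m.coefficients, 0)
        assert m.intercept == pytest.approx(y.mean())

    def test_zero_penalty_is_ols(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        m = elastic_net_fit(X, y, alpha=0.7, lam=0.0)
        beta = np.linalg.lstsq(np.c_[np.ones(30), X], y, rcond=None)[0]
        assert np.allclose(m.coefficients, beta[1:], atol=1e-8)
        assert m.intercept == pytest.approx(beta[0])

    @staticmethod
    def objective(beta, b0, X, y, alpha, lam):
        resid = y - X @ beta - b0
        return (
            0.5 * np.mean(resid**2)
            + lam * ((1 - alpha) * np.sum(beta**2) + alpha * np.sum(np.abs(beta)))
        )

    @pytest.mark.parametrize("alpha,lam", [(1.0, 0.05), (0.5, 0.1), (0.0, 0.2)])
    def test_matches_numerical_optimizer(self, alpha, lam, rng):
        X = rng.standard_normal((25, 4))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, 0] - 0.5 * X[:, 1] + 0.3 * rng.standard_normal(25)
        m = elastic_net_fit(X, y, alpha=alpha, lam=lam)

        def f(params):
            return self.objective(params[1:], params[0], X, y, alpha, lam)

        res = optimize.minimize(f, np.zeros(5), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14,
                                         "maxiter": 50000, "maxfev": 50000})
        ours = f(np.r_[m.intercept, m.coefficients])
        assert ours <= res.fun + 1e-8
        # and no direction on a local grid improves the objective
        for j in range(4):
            for eps in (-1e-4, 1e-4):
                b = m.coefficients.copy()
                b[j] += eps
                assert self.objective(b, m.intercept, X, y, alpha, lam) >= ours - 1e-12

    def test_objective_no_worse_than_zero_vector(self, rng):
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        m = elastic_net_fit(X, y, alpha=0.8, lam=0.05)
        at_sol = self.objective(m.coefficients, m.intercept, X, y, 0.8, 0.05)
        at_zero = self.objective(np.zeros(6), y.mean(), X, y, 0.8, 0.05)
        assert at_sol <= at_zero + 1e-12

    @pytest.mark.parametrize("alpha,lam", [(-0.1, 1.0), (1.1, 1.0), (0.5, -1.0)])
    def test_invalid_parameters_rejected(self, alpha, lam):
        with pytest.raises(ValueError):
            elastic_net_fit(np.ones((5, 1)), np.ones(5), alpha=alpha, lam=lam)


class TestSelectAlphaLambda:
    def test_strong_signal_features_retained(self, rng):
        n, p = 40, 10
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = 2 * X[:, 0] - 2 * X[:, 1] + 0.3 * rng.standard_normal(n)
        alpha, lam, _ = select_alpha_lambda(X, y, rng=np.random.default_rng(0))
        m = elastic_net_fit(X, y, alpha, lam)
        assert m.coefficients[0] != 0 and m.coefficients[1] != 0

    def test_pure_noise_keeps_regularized_model(self, rng):
        n, p = 40, 10
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        alpha, lam, cv_rms = select_alpha_lambda(X, y, rng=np.random.default_rng(0))
        # no exploitable signal: CV error is not better than the response SD
        assert cv_rms >= 0.85 * y.std()

    def test_tie_rule_smallest_alpha_then_largest_lambda(self):
        # constant response: every (alpha, lambda) scores identically, so
        # the winner must be the first candidate scanned
        X = np.random.default_rng(3).standard_normal((30, 4))
        y = np.full(30, 1.5)
        alpha, lam, _ = select_alpha_lambda(X, y, rng=np.random.default_rng(0))
        assert alpha == 0.0
        from drugsense.learners import _lambda_grid
        assert lam == pytest.approx(_lambda_grid(X, y, 0.0, 20, 1e-3)[0])


class TestLassoSparsitySweep:
    def test_planted_signal_and_path_properties(self, rng):
        n, p = 45, 30
        # orthogonal design: the lasso path is then coordinatewise soft
        # thresholding, so the support grows monotonically as λ shrinks
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        X = Q * np.sqrt(n)
        beta = np.zeros(p)
        beta[:5] = [1.0, -1.0, 0.8, -0.8, 0.6]
        y = X @ beta + 0.4 * rng.standard_normal(n)
        table = lasso_sparsity_sweep(X, y, rng=np.random.default_rng(0))
        # support size is non-increasing in lambda (rows ordered lambda-desc)
        assert (np.diff(table["n_nonzero"]) >= 0).all()
        # the heaviest penalty gives the empty model = fold-mean baseline
        assert table["n_nonzero"].iloc[0] == 0
        folds = fold_indices(n, 10, np.random.default_rng(0))
        baseline = np.empty(n)
        for te in folds:
            tr = np.setdiff1d(np.arange(n), te)
            baseline[te] = y[tr].mean()
        assert table["cv_rms"].iloc[0] == pytest.approx(
            float(np.sqrt(np.mean((baseline - y) ** 2)))
        )
        # close-to-optimal performance with support <= 10
        small = table[(table["n_nonzero"] >= 1) & (table["n_nonzero"] <= 10)]
        assert small["cv_rho"].max() >= 0.9 * table["cv_rho"].max()


class TestMaxCorr:
    def test_exact_feature_recovered(self, rng):
        X = rng.standard_normal((20, 5))
        y = X[:, 3].copy()
        m = max_corr_fit(X, y)
        assert m.feature_index == 3
        assert np.allclose(m.predict(X), y, atol=1e-12)

    def test_tie_broken_by_lowest_index(self, rng):
        x = rng.standard_normal(15)
        X = np.c_[rng.standard_normal(15), x, x]  # identical |r| at 1 and 2
        y = x + 0.1 * rng.standard_normal(15)
        m = max_corr_fit(X, y)
        assert m.feature_index == 1

    def test_selection_power_among_noise(self):
        # 50 noise features + one true r=0.9 feature: selected in >= 95%
        hits = 0
        n_sim = 200
        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            n = 30
            y = rng.standard_normal(n)
            signal = 0.9 * (y - y.mean()) / y.std() + np.sqrt(1 - 0.81) * (
                rng.standard_normal(n)
            )
            X = np.c_[rng.standard_normal((n, 50)), signal]
            if max_corr_fit(X, y).feature_index == 50:
                hits += 1
        assert hits / n_sim >= 0.95

    def test_constant_features_rejected(self):
        with pytest.raises(ValueError):
            max_corr_fit(np.ones((10, 3)), np.arange(10, dtype=float))

    def test_too_few_lines_rejected(self):
        with pytest.raises(ValueError):
            max_corr_fit(np.ones((2, 3)), np.ones(2))
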