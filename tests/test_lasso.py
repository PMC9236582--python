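"""Positive-Lasso path, standardization, sample selection and the estimator."""

import warnings

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from sitelasso import lasso, models, trees
from sitelasso.errors import UnreachableFractionError, ValidationError
from sitelasso.simulate import simulate_alignment


def _toy_regression(rng, n=60, m=30, k=4, noise=0.05):
    X = rng.normal(size=(n, m))
    beta = np.zeros(m)
    beta[:k] = rng.uniform(0.5, 2.0, k)
    y = 3.0 + X @ beta + rng.normal(scale=noise, size=n)
    return X, y, beta


class TestTrainingSet:
    def test_y_equals_row_sums_and_determinism(self):
        model = models.jukes_cantor(alpha=0.9, n_categories=4)
        true = trees.random_tree([f"t{i}" for i in range(6)], 1, 0.1)
        aln = simulate_alignment(true, model, 80, 2).alignment
        ts1 = lasso.build_training_set(aln, model, eta=10, rng_seed=5)
        ts2 = lasso.build_training_set(aln, model, eta=10, rng_seed=5)
        assert np.array_equal(ts1.X, ts2.X)
        assert np.array_equal(ts1.y, ts1.X.sum(axis=1))
        assert len(ts1.trees) == 10

    def test_eta_defaults_follow_alignment_depth(self):
        assert lasso.default_eta(15) == 2000
        assert lasso.default_eta(30) == 4000
        assert lasso.default_eta(60) == 4000

    def test_too_small_eta_rejected(self):
        model = models.jukes_cantor()
        true = trees.random_tree(list("abcd"), 0, 0.1)
        aln = simulate_alignment(true, model, 10, 1).alignment
        with pytest.raises(ValidationError):
            lasso.build_training_set(aln, model, eta=1)


class TestStandardization:
    def test_unit_norms_and_centering(self, rng):
        X, y, _ = _toy_regression(rng)
        std = lasso.standardize_design(X, y)
        assert np.allclose(np.linalg.norm(std.X, axis=0), 1.0, atol=1e-10)
        assert np.allclose(std.X.sum(axis=0), 0.0, atol=1e-10)
        assert std.y_centered.mean() == pytest.approx(0.0, abs=1e-10)

    def test_constant_column_flagged_and_zeroed(self, rng):
        X, y, _ = _toy_regression(rng)
        X[:, 5] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            std = lasso.standardize_design(X, y)
        assert not std.valid[5]
        assert np.allclose(std.X[:, 5], 0.0)

    def test_unstandardize_round_trip_recovers_known_model(self, rng):
        # y generated by a known non-negative linear model with zero noise:
        # translating its standardized coefficients back must reproduce it
        X, y, beta = _toy_regression(rng, noise=0.0)
        std = lasso.standardize_design(X, y)
        beta_std = beta * std.column_norms
        path = lasso.LassoPath(np.array([0.0]), beta_std[None, :],
                               np.array([(beta_std > 0).sum()]), np.array([True]))
        sample = lasso.select_sample(path, 1e-9, std)
        assert np.allclose(sample.weights, beta[beta > 0], atol=1e-8)
        assert sample.intercept == pytest.approx(3.0, abs=1e-8)
        pred = sample.intercept + X[:, sample.sites0] @ sample.weights
        assert np.allclose(pred, y, atol=1e-8)


class TestCoordinateDescent:
    def test_all_zero_at_grid_maximum(self, rng):
        X, y, _ = _toy_regression(rng)
        std = lasso.standardize_design(X, y)
        lam_max = lasso.lambda_grid(std.X, std.y_centered)[0]
        beta, _, ok, _ = lasso.positive_cd(std.X, std.y_centered, lam_max)
        assert ok and (beta == 0).all()
        # marginally below the maximum the solution activates
        beta2, *_ = lasso.positive_cd(std.X, std.y_centered, lam_max * 0.99)
        assert (beta2 > 0).any()

    def test_objective_non_increasing_per_sweep(self, rng):
        X, y, _ = _toy_regression(rng, n=40, m=25)
        std = lasso.standardize_design(X, y)
        lam = lasso.lambda_grid(std.X, std.y_centered)[30]
        _, _, _, obj = lasso.positive_cd(std.X, std.y_centered, lam,
                                         record_objective=True)
        assert (np.diff(obj) <= 1e-9).all()

    def test_matches_sklearn_positive_lasso(self, rng):
        # independent solver cross-check; sklearn minimizes
        # 1/(2n) ||y - Xb||^2 + alpha ||b||_1, i.e. alpha = lambda / (2n)
        X, y, _ = _toy_regression(rng, n=80, m=40)
        std = lasso.standardize_design(X, y)
        for lam in [20.0, 5.0, 0.5]:
            mine, _, _, _ = lasso.positive_cd(std.X, std.y_centered, lam,
                                              tol=1e-7, max_sweeps=20000)
            sk = Lasso(alpha=lam / (2 * len(y)), positive=True, fit_intercept=False,
                       tol=1e-12, max_iter=200000).fit(std.X, std.y_centered)
            assert np.abs(mine - sk.coef_).max() < 1e-6

    def test_duplicated_column_block_recovers_weight_mass(self, rng):
        # one predictive column duplicated 50 times: the block's total weight
        # must land within 5% of the true coefficient
        n = 100
        x = rng.normal(size=n)
        X = np.column_stack([np.tile(x, (50, 1)).T, rng.normal(size=(n, 20))])
        true_coef = 2.0
        y = true_coef * x + rng.normal(scale=0.01, size=n)
        std = lasso.standardize_design(X, y)
        lam = lasso.lambda_grid(std.X, std.y_centered)[60]
        beta, *_ = lasso.positive_cd(std.X, std.y_centered, lam, tol=1e-6,
                                     max_sweeps=20000)
        weights = beta / std.column_norms
        block = weights[:50].sum()
        assert (beta[:50] > 0).sum() >= 1
        assert abs(block - true_coef) / true_coef < 0.05


class TestPath:
    def test_nonzero_count_weakly_increases(self, rng):
        X, y, _ = _toy_regression(rng, n=80, m=40, k=8)
        std = lasso.standardize_design(X, y)
        path = lasso.fit_positive_lasso_path(std.X, std.y_centered)
        assert path.n_nonzero[0] == 0
        dips = np.diff(path.n_nonzero.astype(int))
        assert dips.min() >= -max(3, int(0.005 * X.shape[1]))  # solver tolerance
        assert path.n_nonzero[-1] > 0

    def test_ols_limit_fits_training_data(self, rng):
        # smallest penalties with eta >> active columns: essentially OLS
        X, y, _ = _toy_regression(rng, n=100, m=15, k=5, noise=0.01)
        std = lasso.standardize_design(X, y)
        path = lasso.fit_positive_lasso_path(std.X, std.y_centered)
        pred = std.X @ path.coefs[-1]
        ss_res = ((std.y_centered - pred) ** 2).sum()
        ss_tot = (std.y_centered ** 2).sum()
        assert 1 - ss_res / ss_tot >= 0.999


class TestSelectSample:
    def test_first_crossing_and_achieved_fraction(self, rng):
        X, y, _ = _toy_regression(rng, n=80, m=40, k=8)
        std = lasso.standardize_design(X, y)
        path = lasso.fit_positive_lasso_path(std.X, std.y_centered)
        sample = lasso.select_sample(path, 0.1, std)
        assert sample.zeta_achieved >= 0.1
        g = np.nonzero(path.lambdas == sample.lam)[0][0]
        assert (path.n_nonzero[:g] / 40 < 0.1).all()  # largest qualifying lambda
        assert (sample.weights > 0).all()
        assert sample.tau == len(sample.weights)

    def test_unreachable_fraction_raises(self, rng):
        X, y, _ = _toy_regression(rng, n=30, m=40, k=3)
        std = lasso.standardize_design(X, y)
        path = lasso.fit_positive_lasso_path(std.X, std.y_centered)
        top = path.n_nonzero.max() / 40
        with pytest.raises(UnreachableFractionError):
            lasso.select_sample(path, min(1.0, top + 0.2), std)

    def test_json_round_trip(self, tmp_path, rng):
        X, y, _ = _toy_regression(rng)
        sampler = lasso.LassoSiteSampler(zeta=0.2).fit(X, y)
        sample = sampler.to_sample(eta=60, seed=1, model_id="toy")
        path = tmp_path / "s.json"
        sample.to_json(path)
        back = lasso.LassoSample.from_json(path)
        assert np.array_equal(back.sites, sample.sites)
        assert np.allclose(back.weights, sample.weights)
        assert back.intercept == pytest.approx(sample.intercept)
        assert back.eta == 60


class TestApproximation:
    def test_identity_sample_is_exact(self, rng):
        vals = rng.normal(size=50)
        sample = lasso.identity_sample(50)
        assert lasso.approximate_log_likelihood(vals, sample) == pytest.approx(vals.sum())

    def test_intercept_does_not_change_ranking(self, rng):
        X, y, _ = _toy_regression(rng)
        sampler = lasso.LassoSiteSampler(zeta=0.2).fit(X, y)
        sample = sampler.to_sample()
        with_b0 = [lasso.approximate_log_likelihood(row, sample) for row in X]
        without = [lasso.approximate_log_likelihood(row, sample, use_intercept=False)
                   for row in X]
        assert np.argmax(with_b0) == np.argmax(without)
        assert np.allclose(np.array(with_b0) - np.array(without), sample.intercept)

    def test_out_of_range_site_rejected(self):
        sample = lasso.identity_sample(10)
        with pytest.raises(ValidationError):
            lasso.approximate_log_likelihood(np.zeros(5), sample)

    def test_standardized_model_reproduced_after_unstandardizing(self, rng):
        X, y, _ = _toy_regression(rng, n=70, m=25, k=5)
        std = lasso.standardize_design(X, y)
        path = lasso.fit_positive_lasso_path(std.X, std.y_centered)
        g = 70
        sample_like = path.coefs[g]
        fitted_std = std.y_mean + std.X @ sample_like
        sample = lasso.LassoPath(path.lambdas[g:g + 1], path.coefs[g:g + 1],
                                 path.n_nonzero[g:g + 1], path.converged[g:g + 1])
        s = lasso.select_sample(sample, 1e-9, std)
        fitted_orig = s.intercept + X[:, s.sites0] @ s.weights
        assert np.allclose(fitted_std, fitted_orig, atol=1e-8)


class TestEstimatorInterface:
    def test_sklearn_contract(self, rng):
        X, y, _ = _toy_regression(rng)
        est = lasso.LassoSiteSampler(zeta=0.15)
        assert est.get_params()["zeta"] == 0.15
        est.set_params(zeta=0.2).fit(X, y)
        assert est.n_features_in_ == X.shape[1]
        assert est.zeta_achieved_ >= 0.2
        assert est.score(X, y) > 0.99  # R^2 on training data
        pred = est.predict(X)
        assert pred.shape == y.shape

    def test_default_response_is_row_sums(self, rng):
        X = rng.normal(size=(40, 20))
        est = lasso.LassoSiteSampler(zeta=0.3).fit(X)
        manual = lasso.LassoSiteSampler(zeta=0.3).fit(X, X.sum(axis=1))
        assert np.array_equal(est.sites_, manual.sites_)
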