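"""Tests of the EMBanded model / results layer: fitting behaviour,
prediction, equivariance, reporting."""

import numpy as np
import pytest

from bandedreg import (
    DimensionError,
    EMBanded,
    GroupedDesign,
    Hyperpriors,
    fit_em,
    ridge_fit,
)

from conftest import random_instance


class TestFitBehaviour:
    @pytest.mark.parametrize("seed", range(6))
    def test_objective_trace_non_decreasing(self, seed):
        design, y, _ = random_instance(seed)
        res = fit_em(design, y, Hyperpriors(gamma=1e-3), max_iter=60)
        diffs = np.diff(res.objective_trace)
        tol = 1e-8 * (1.0 + np.abs(res.objective_trace[:-1]))
        assert np.all(diffs >= -tol)

    @pytest.mark.parametrize("seed", range(6))
    def test_hyperparameter_traces_positive_and_bounded(self, seed):
        design, y, _ = random_instance(seed)
        hp = Hyperpriors(eta=0.3, tau=0.7, phi=0.2, kappa=1.1)
        res = fit_em(design, y, hp, max_iter=40)
        assert np.all(res.lambda_trace > 0)
        assert np.all(res.nu_trace > 0)
        # Inverse-Gamma scale terms bound the updates away from zero
        lam_floor = 2 * hp.tau / (design.sizes + 2 * hp.eta + 2)
        assert np.all(res.lambda_trace[1:] >= lam_floor - 1e-15)
        nu_floor = 2 * hp.kappa / (design.n_obs + 2 + 2 * hp.phi)
        assert np.all(res.nu_trace[1:] >= nu_floor - 1e-15)
        assert res.n_iter <= 40

    def test_convergence_flag_and_stop_reason(self):
        design, y, _ = random_instance(11)
        res = fit_em(design, y, Hyperpriors(gamma=1e-2), max_iter=500, tol=1e-10)
        assert res.converged
        assert res.stop_reason == "hyperparameter_tolerance"
        capped = fit_em(design, y, Hyperpriors(gamma=1e-2), max_iter=3)
        assert capped.n_iter == 3 and not capped.converged

    def test_zero_targets_collapse_to_prior_floors(self):
        rng = np.random.default_rng(4)
        d = GroupedDesign.from_sizes(rng.standard_normal((30, 6)), [3, 3])
        g = 1e-4
        res = fit_em(d, np.zeros(30), Hyperpriors(gamma=g), max_iter=300)
        assert np.max(np.abs(res.coef)) < 1e-8
        floor = 2 * g / (3 + 2 * g + 2)
        np.testing.assert_allclose(res.lambdas, floor, rtol=0.2)

    def test_ridge_equivalence_via_pinned_hyperpriors(self):
        # enormous prior shape pins lambda and nu at tau/eta and kappa/phi
        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 6))
        d = GroupedDesign.from_sizes(X, [6])
        y = rng.standard_normal(40)
        lam0, nu0 = 0.5, 2.0
        big = 1e12
        hp = Hyperpriors(eta=big, tau=lam0 * big, phi=big, kappa=nu0 * big)
        res = fit_em(d, y, hp, max_iter=5)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        w = ridge_fit(Xc, yc, nu0 / lam0).weights
        np.testing.assert_allclose(res.coef, w, atol=1e-8)

    def test_group_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        d = GroupedDesign.from_sizes(rng.standard_normal((50, 9)), [4, 3, 2])
        y = d.X @ rng.standard_normal(9) + rng.standard_normal(50)
        res = fit_em(d, y, Hyperpriors(gamma=1e-3), max_iter=80)
        order = [2, 0, 1]
        res_p = fit_em(d.permuted(order), y, Hyperpriors(gamma=1e-3), max_iter=80)
        np.testing.assert_allclose(res_p.lambdas, res.lambdas[order], atol=1e-10)
        for name in d.names:
            np.testing.assert_allclose(
                res_p.coef[res_p.design.group_slice(name)],
                res.coef_group(name),
                atol=1e-10,
            )

    def test_nonfinite_target_rejected(self):
        d = GroupedDesign.from_sizes(np.eye(3), [3])
        with pytest.raises(Exception, match="finite"):
            EMBanded(d, np.array([1.0, np.nan, 0.0]))


class TestPredict:
    @pytest.fixture
    def fitted(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((60, 5)) + 2.0
        d = GroupedDesign.from_sizes(X, [3, 2])
        y = X @ np.array([1.0, -1.0, 0.5, 0.0, 0.0]) + 0.1 * rng.standard_normal(60) + 5.0
        return EMBanded(d, y, hyperpriors=Hyperpriors(gamma=1e-4)).fit()

    def test_training_row_matches_linear_form(self, fitted):
        X = fitted.model.design.X  # centered internally
        row = X[3] + fitted.model.x_means
        pred = fitted.predict(row[None, :])
        expected = X[3] @ fitted.coef + fitted.model.y_means
        assert pred[0] == pytest.approx(float(np.ravel(expected)[0]), rel=1e-10)

    def test_centered_zero_row_predicts_training_mean_with_noise_variance(self, fitted):
        row = fitted.model.x_means[None, :]  # zero after centering
        point, cov = fitted.predict(row, mode="distribution")
        assert point[0] == pytest.approx(float(np.ravel(fitted.model.y_means)[0]), rel=1e-10)
        assert cov[0, 0] == pytest.approx(fitted.nu, rel=1e-8)

    def test_predictive_variance_floor_and_psd(self, fitted):
        rng = np.random.default_rng(0)
        Xn = rng.standard_normal((7, 5))
        _, cov = fitted.predict(Xn, mode="distribution")
        np.testing.assert_allclose(cov, cov.T, atol=1e-10)
        assert np.all(np.diag(cov) >= fitted.nu - 1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-10)

    def test_scalar_design_variance_expansion(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 1))
        d = GroupedDesign.from_sizes(X, [1])
        y = 2.0 * X[:, 0] + 0.3 * rng.standard_normal(20)
        res = EMBanded(d, y, assume_centered=False).fit()
        xh = np.array([[1.5]])
        _, cov = res.predict(xh, mode="distribution")
        s = float(res.posterior.Sigma[0, 0])
        xc = 1.5 - res.model.x_means[0]
        assert cov[0, 0] == pytest.approx(res.nu + xc**2 * s, rel=1e-10)

    def test_column_mismatch_raises(self, fitted):
        with pytest.raises(DimensionError):
            fitted.predict(np.ones((2, 4)))


class TestReporting:
    def test_summary_names_groups_and_reports_convergence(self):
        design, y, _ = random_instance(2)
        res = fit_em(design, y, max_iter=30)
        text = res.summary()
        for name in design.names:
            assert name in text
        assert "nu" in text and "lambda" in text

    def test_weight_table_shape_and_groups(self):
        design, y, _ = random_instance(2)
        res = fit_em(design, y, max_iter=10)
        tab = res.weight_table()
        assert len(tab) == design.n_predictors
        assert set(tab["group"]) == set(design.names)
        np.testing.assert_allclose(tab["weight"].to_numpy(), res.coef)

    def test_diagnostics_round_trip_json(self, tmp_path):
        import json

        design, y, _ = random_instance(2)
        res = fit_em(design, y, max_iter=10)
        p = tmp_path / "diag.json"
        res.to_json(p)
        loaded = json.loads(p.read_text())
        assert loaded["n_iter"] == res.n_iter
        np.testing.assert_allclose(
            list(loaded["lambdas"].values()), res.lambdas
        )

    def test_from_dataframe_matches_array_api(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 4))
        y = X @ np.array([1.0, 0.5, 0.0, 0.0]) + 0.1 * rng.standard_normal(40)
        df = pd.DataFrame(X, columns=["a1", "a2", "b1", "b2"])
        df["resp"] = y
        m1 = EMBanded.from_dataframe(
            df, {"A": ["a1", "a2"], "B": ["b1", "b2"]}, "resp"
        ).fit(max_iter=25)
        m2 = EMBanded(
            [("A", X[:, :2]), ("B", X[:, 2:])], y
        ).fit(max_iter=25)
        np.testing.assert_array_equal(m1.coef, m2.coef)
        np.testing.assert_array_equal(m1.lambdas, m2.lambdas)
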