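"""Unit tests of the EM building blocks: E-step posterior, M-step updates,
marginal objective evaluation."""

import numpy as np
import pytest
from scipy import stats

from bandedreg import (
    GroupedDesign,
    Hyperpriors,
    NoiseState,
    NumericalError,
    PriorState,
    SmoothnessSpec,
    log_marginal_objective,
    posterior_update,
    update_lambda,
    update_nu,
)
from bandedreg.em import PosteriorState

from conftest import random_instance


def _identity_problem():
    d = GroupedDesign.from_sizes(np.eye(2), [2])
    prior = PriorState.from_spec(d, 1.0)
    return d, np.array([1.0, 1.0]), prior, NoiseState(1.0)


class TestPosteriorUpdate:
    def test_identity_design_closed_form(self):
        d, y, prior, noise = _identity_problem()
        post = posterior_update(d, y, prior, noise)
        np.testing.assert_allclose(post.Sigma, 0.5 * np.eye(2), atol=1e-12)
        np.testing.assert_allclose(post.mu, [0.5, 0.5], atol=1e-12)

    def test_zero_design_returns_prior(self):
        d = GroupedDesign.from_sizes(np.zeros((4, 3)), [2, 1])
        prior = PriorState.from_spec(d, np.array([2.0, 5.0]))
        post = posterior_update(d, np.ones(4), prior, NoiseState(1.0))
        np.testing.assert_allclose(post.mu, 0.0, atol=1e-12)
        np.testing.assert_allclose(post.Sigma, prior.Lambda, atol=1e-10)

    def test_huge_noise_variance_shrinks_mean_to_zero(self):
        rng = np.random.default_rng(0)
        d = GroupedDesign.from_sizes(rng.standard_normal((10, 4)), [4])
        prior = PriorState.from_spec(d, 1.0)
        post = posterior_update(d, rng.standard_normal(10), prior, NoiseState(1e12))
        assert np.max(np.abs(post.mu)) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_defining_linear_system_residual(self, seed):
        design, y, _ = random_instance(seed)
        rng = np.random.default_rng(seed + 100)
        prior = PriorState.from_spec(design, rng.uniform(0.1, 3.0, design.n_groups))
        nu = float(rng.uniform(0.5, 2.0))
        post = posterior_update(design, y, prior, NoiseState(nu))
        A = prior.Lambda_inv + design.X.T @ design.X / nu
        b = design.X.T @ y / nu
        resid = np.linalg.norm(A @ post.mu - b) / np.linalg.norm(b)
        assert resid <= 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_direct_and_woodbury_routes_agree(self, seed):
        # fat design: more predictors than observations
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((20, 60))
        d = GroupedDesign.from_sizes(X, [20, 25, 15])
        y = rng.standard_normal(20)
        prior = PriorState.from_spec(
            d, rng.uniform(0.2, 2.0, 3), SmoothnessSpec({"F2": 3.0})
        )
        noise = NoiseState(float(rng.uniform(0.5, 2.0)))
        direct = posterior_update(d, y, prior, noise, route="direct")
        lemma = posterior_update(d, y, prior, noise, route="woodbury")
        np.testing.assert_allclose(direct.mu, lemma.mu, atol=1e-8)
        np.testing.assert_allclose(direct.Sigma, lemma.Sigma, atol=1e-8)

    def test_sigma_symmetric_positive_definite(self):
        design, y, _ = random_instance(7)
        prior = PriorState.from_spec(design, 1.0)
        post = posterior_update(design, y, prior, NoiseState(1.0))
        np.testing.assert_allclose(post.Sigma, post.Sigma.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(post.Sigma) > 0)

    def test_group_views_are_exact_slices(self):
        design, y, _ = random_instance(3)
        prior = PriorState.from_spec(design, 1.0)
        post = posterior_update(design, y, prior, NoiseState(1.0))
        for j in range(design.n_groups):
            sl = design.group_slice(j)
            np.testing.assert_array_equal(post.mu_group(j), post.mu[sl])
            np.testing.assert_array_equal(post.Sigma_group(j), post.Sigma[sl, sl])


class TestMStepUpdates:
    def _posterior(self, design, mu, Sigma):
        return PosteriorState(mu=mu, Sigma=Sigma, design=design)

    def test_lambda_zero_mean_identity_blocks(self):
        d = GroupedDesign.from_sizes(np.zeros((3, 2)), [2])
        prior = PriorState.from_spec(d, 1.0)
        post = self._posterior(d, np.zeros(2), np.eye(2))
        hp = Hyperpriors(gamma=1e-300)  # tau = eta ~ 0
        assert update_lambda(post, prior, hp, 0) == pytest.approx(0.5, rel=1e-12)

    def test_lambda_scalar_group(self):
        d = GroupedDesign.from_sizes(np.zeros((3, 1)), [1])
        prior = PriorState.from_spec(d, 1.0)
        post = self._posterior(d, np.array([2.0]), np.array([[1.0]]))
        hp = Hyperpriors(gamma=1e-300)
        assert update_lambda(post, prior, hp, 0) == pytest.approx(5.0 / 3.0, rel=1e-12)

    def test_lambda_lower_bound_at_degenerate_posterior(self):
        d = GroupedDesign.from_sizes(np.zeros((3, 2)), [2])
        prior = PriorState.from_spec(d, 1.0)
        post = self._posterior(d, np.zeros(2), np.zeros((2, 2)))
        g = 0.25
        hp = Hyperpriors(gamma=g)
        expected = 2 * g / (2 + 2 * g + 2)
        assert update_lambda(post, prior, hp, 0) == pytest.approx(expected, rel=1e-12)

    def test_nu_arithmetic(self):
        # rss 2, trace term 1, M=3, no prior mass -> 3/5
        rng = np.random.default_rng(0)
        X = np.eye(3)
        d = GroupedDesign.from_sizes(X, [3])
        mu = np.zeros(3)
        y = np.array([1.0, 1.0, 0.0])  # rss = 2
        Sigma = np.diag([1.0, 0.0, 0.0])  # Tr(X'X Sigma) = 1
        post = self._posterior(d, mu, Sigma)
        hp = Hyperpriors(gamma=1e-300)
        assert update_nu(d, y, post, hp) == pytest.approx(0.6, rel=1e-12)

    def test_nu_lower_bound_with_perfect_fit(self):
        d = GroupedDesign.from_sizes(np.eye(3), [3])
        y = np.array([1.0, 2.0, 3.0])
        post = self._posterior(d, y.copy(), np.zeros((3, 3)))
        hp = Hyperpriors(eta=1e-8, tau=1e-8, phi=0.5, kappa=2.0)
        expected = 2 * 2.0 / (3 + 2 + 2 * 0.5)
        assert update_nu(d, y, post, hp) == pytest.approx(expected, rel=1e-12)

    def test_nu_zero_design_is_target_power(self):
        d = GroupedDesign.from_sizes(np.zeros((4, 2)), [2])
        y = np.array([1.0, -1.0, 1.0, -1.0])  # ||y||^2 = 4
        post = self._posterior(d, np.zeros(2), np.eye(2))
        hp = Hyperpriors(gamma=1e-300)
        assert update_nu(d, y, post, hp) == pytest.approx(4.0 / 6.0, rel=1e-12)


class TestMarginalObjective:
    def test_zero_design_reduces_to_iid_gaussian_plus_priors(self):
        rng = np.random.default_rng(5)
        d = GroupedDesign.from_sizes(np.zeros((6, 3)), [3])
        y = rng.standard_normal(6)
        hp = Hyperpriors(gamma=1e-2)
        lam, nu = 1.7, 0.9
        prior = PriorState.from_spec(d, lam)
        val = log_marginal_objective(d, y, prior, NoiseState(nu), hp)
        expected = (
            stats.norm.logpdf(y, scale=np.sqrt(nu)).sum()
            + stats.invgamma.logpdf(lam, hp.eta, scale=hp.tau)
            + stats.invgamma.logpdf(nu, hp.phi, scale=hp.kappa)
        )
        assert val == pytest.approx(expected, rel=1e-10)

    def test_evaluation_routes_agree(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((10, 6))
        d = GroupedDesign.from_sizes(X, [4, 2])
        y = rng.standard_normal(10)
        hp = Hyperpriors(gamma=1e-3)
        prior = PriorState.from_spec(d, np.array([0.4, 2.2]), SmoothnessSpec({"F1": 2.0}))
        noise = NoiseState(1.4)
        direct = log_marginal_objective(d, y, prior, noise, hp, route="direct")
        lemma = log_marginal_objective(d, y, prior, noise, hp, route="lemma")
        assert direct == pytest.approx(lemma, abs=1e-6)

    def test_nonfinite_state_raises(self):
        d = GroupedDesign.from_sizes(np.eye(2), [2])
        prior = PriorState.from_spec(d, 1.0)
        bad = np.full((2, 2), np.nan)
        with pytest.raises(NumericalError):
            from bandedreg._linalg import chol_factor

            chol_factor(bad)
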