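import numpy as np
import pytest

import voxelbma as vb
from voxelbma.bma import ModelSpace

from _oracles import (
    brute_force_pips,
    quadrature_log_bayes_factor,
    quadrature_posterior_slope_mean,
)


class TestDefaultG:
    @pytest.mark.parametrize(
        "n,k,expected",
        [(57, 11, 1 / 121), (200, 5, 1 / 200), (121, 11, 1 / 121)],
    )
    def test_formula(self, n, k, expected):
        assert vb.default_g(n, k).g == pytest.approx(expected, rel=0, abs=0)

    @pytest.mark.parametrize("n,k", [(1, 3), (0, 2), (10, 0)])
    def test_degenerate_sizes_rejected(self, n, k):
        with pytest.raises(ValueError):
            vb.default_g(n, k)

    def test_non_positive_g_rejected(self):
        with pytest.raises(ValueError):
            vb.GPrior(0.0)


class TestLogMarginalLikelihood:
    def test_null_model_closed_form(self, small_regression):
        y, X = small_regression
        prior = vb.default_g(*X.shape)
        null = vb.RegressionModel(mask=0, k=X.shape[1])
        yc = y - y.mean()
        expected = -0.5 * (len(y) - 1) * np.log(yc @ yc)
        assert vb.log_marginal_likelihood(y, X, null, prior) == pytest.approx(expected)

    def test_scaling_y_shifts_all_marginals_equally(self, small_regression):
        y, X = small_regression
        prior = vb.default_g(*X.shape)
        models = [vb.RegressionModel(mask=m, k=4) for m in range(16)]
        base = np.array([vb.log_marginal_likelihood(y, X, m, prior) for m in models])
        scaled = np.array(
            [vb.log_marginal_likelihood(2.0 * y, X, m, prior) for m in models]
        )
        shifts = scaled - base
        assert np.allclose(shifts, shifts[0])

    def test_matches_quadrature_oracle(self):
        """Closed-form log Bayes factor vs 3-D numerical integration, n=6."""
        x = np.array([0.3, -1.2, 0.7, 1.5, -0.4, -0.9])
        y = np.array([0.42, 0.38, 0.44, 0.47, 0.40, 0.39])
        g = 0.25
        prior = vb.GPrior(g)
        X = x.reshape(-1, 1)
        closed = vb.log_marginal_likelihood(
            y, X, vb.RegressionModel(mask=1, k=1), prior
        ) - vb.log_marginal_likelihood(y, X, vb.RegressionModel(mask=0, k=1), prior)
        oracle = quadrature_log_bayes_factor(y, x, g)
        assert np.exp(closed) == pytest.approx(np.exp(oracle), rel=0.01)

    def test_rank_deficient_submatrix_gets_minus_inf(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=10)
        X = np.column_stack([x1, 2.0 * x1])
        y = 0.4 + rng.normal(0, 0.05, 10)
        prior = vb.GPrior(0.01)
        with pytest.warns(UserWarning, match="rank-deficient"):
            lml = vb.log_marginal_likelihood(
                y, X, vb.RegressionModel(mask=3, k=2), prior
            )
        assert lml == -np.inf

    def test_constant_response_rejected(self, small_regression):
        _, X = small_regression
        prior = vb.default_g(*X.shape)
        with pytest.raises(vb.ConstantResponseError):
            vb.log_marginal_likelihood(
                np.full(X.shape[0], 0.3), X, vb.RegressionModel(mask=1, k=4), prior
            )


class TestEnumerateModels:
    def test_k11_enumerates_2048_models(self, default_design):
        rng = np.random.default_rng(1)
        y = 0.45 + rng.normal(0, 0.02, default_design.n)
        post = vb.enumerate_models(y, default_design, vb.default_g(57, 11))
        assert post.n_models == 2048
        assert post.posterior_probs.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(post.prior_probs == 1 / 2048)

    def test_identical_log_marginals_normalize_to_uniform(self):
        # normalization contract checked in isolation from the data model
        lml = np.full(2048, -123.456)
        probs = np.exp(lml - lml.max())
        probs /= probs.sum()
        post = vb.ModelPosterior(
            log_marginals=lml, posterior_probs=probs,
            prior_probs=np.full(2048, 1 / 2048),
        )
        assert np.allclose(post.posterior_probs, 1 / 2048)

    def test_argmax_posterior_is_argmax_log_marginal(self, small_regression):
        y, X = small_regression
        post = vb.enumerate_models(y, X, vb.default_g(*X.shape))
        assert np.argmax(post.posterior_probs) == np.argmax(post.log_marginals)

    def test_strong_single_covariate_signal_dominates(self):
        rng = np.random.default_rng(99)
        X = rng.normal(size=(30, 3))
        y = 0.4 + 0.05 * X[:, 0] + rng.normal(0, 1e-4, 30)
        post = vb.enumerate_models(y, X, vb.default_g(30, 3))
        pips = vb.posterior_inclusion_probabilities(post)
        assert pips[0] > 0.99

    def test_enumeration_guard_refuses_large_k(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 21))
        with pytest.raises(ValueError, match="MC3"):
            ModelSpace(X)


class TestPIPs:
    def test_all_mass_on_single_model(self):
        k = 3
        probs = np.zeros(8)
        probs[0b001] = 1.0
        post = vb.ModelPosterior(
            log_marginals=np.where(probs > 0, 0.0, -np.inf),
            posterior_probs=probs, prior_probs=np.full(8, 1 / 8),
        )
        assert np.allclose(vb.posterior_inclusion_probabilities(post), [1, 0, 0])

    def test_uniform_posterior_gives_half_everywhere(self):
        post = vb.ModelPosterior(
            log_marginals=np.zeros(16),
            posterior_probs=np.full(16, 1 / 16),
            prior_probs=np.full(16, 1 / 16),
        )
        assert np.allclose(vb.posterior_inclusion_probabilities(post), 0.5)

    def test_matches_brute_force_indicator_sum_k4(self):
        rng = np.random.default_rng(4)
        probs = rng.dirichlet(np.ones(16))
        post = vb.ModelPosterior(
            log_marginals=np.log(probs), posterior_probs=probs,
            prior_probs=np.full(16, 1 / 16),
        )
        assert np.allclose(
            vb.posterior_inclusion_probabilities(post),
            brute_force_pips(probs, 4),
            atol=1e-12,
        )

    def test_unnormalized_posterior_rejected(self):
        with pytest.raises(ValueError):
            vb.ModelPosterior(
                log_marginals=np.zeros(4),
                posterior_probs=np.array([0.5, 0.5, 0.5, 0.5]),
                prior_probs=np.full(4, 0.25),
            )


class TestModelAveragedCoefficients:
    def test_all_mass_on_null_gives_exact_zeros(self, small_regression):
        y, X = small_regression
        probs = np.zeros(16)
        probs[0] = 1.0
        post = vb.ModelPosterior(
            log_marginals=np.where(probs > 0, 0.0, -np.inf),
            posterior_probs=probs, prior_probs=np.full(16, 1 / 16),
        )
        avg = vb.model_averaged_coefficients(y, X, post, vb.default_g(*X.shape))
        assert np.all(avg.mean == 0)

    def test_single_model_equals_shrunk_ols_and_quadrature(self):
        """Conditional mean = OLS/(1+g), cross-checked by numerical integration."""
        x = np.array([0.3, -1.2, 0.7, 1.5, -0.4, -0.9])
        y = np.array([0.42, 0.38, 0.44, 0.47, 0.40, 0.39])
        g = 0.25
        X = x.reshape(-1, 1)
        probs = np.array([0.0, 1.0])
        post = vb.ModelPosterior(
            log_marginals=np.array([-np.inf, 0.0]),
            posterior_probs=probs, prior_probs=np.array([0.5, 0.5]),
        )
        avg = vb.model_averaged_coefficients(y, X, post, vb.GPrior(g))
        xc = x - x.mean()
        ols = float(xc @ (y - y.mean()) / (xc @ xc))
        assert avg.mean[0] == pytest.approx(ols / (1 + g), rel=1e-12)
        oracle = quadrature_posterior_slope_mean(y, x, g)
        assert avg.mean[0] == pytest.approx(oracle, rel=0.01)

    def test_sign_flip_of_column_flips_coefficient_not_pips(self, small_regression):
        y, X = small_regression
        prior = vb.default_g(*X.shape)
        post = vb.enumerate_models(y, X, prior)
        avg = vb.model_averaged_coefficients(y, X, post, prior)
        pips = vb.posterior_inclusion_probabilities(post)

        X2 = X.copy()
        X2[:, 2] *= -1
        post2 = vb.enumerate_models(y, X2, prior)
        avg2 = vb.model_averaged_coefficients(y, X2, post2, prior)
        pips2 = vb.posterior_inclusion_probabilities(post2)
        assert np.allclose(pips, pips2, atol=1e-10)
        assert avg2.mean[2] == pytest.approx(-avg.mean[2], rel=1e-9)
        others = [0, 1, 3]
        assert np.allclose(avg2.mean[others], avg.mean[others], atol=1e-12)


class TestInvariants:
    def test_location_scale_invariance_of_pips(self, small_regression):
        y, X = small_regression
        prior = vb.default_g(*X.shape)
        post = vb.enumerate_models(y, X, prior)
        post2 = vb.enumerate_models(0.1 + 3.0 * y, X, prior)
        assert np.allclose(post.posterior_probs, post2.posterior_probs, atol=1e-10)
        avg = vb.model_averaged_coefficients(y, X, post, prior)
        avg2 = vb.model_averaged_coefficients(0.1 + 3.0 * y, X, post2, prior)
        assert np.allclose(avg2.mean, 3.0 * avg.mean, rtol=1e-8)

    def test_shrinkage_limits(self, small_regression):
        y, X = small_regression
        probs = np.zeros(16)
        probs[0b1111] = 1.0
        post = vb.ModelPosterior(
            log_marginals=np.where(probs > 0, 0.0, -np.inf),
            posterior_probs=probs, prior_probs=np.full(16, 1 / 16),
        )
        huge = vb.model_averaged_coefficients(y, X, post, vb.GPrior(1e12))
        assert np.all(np.abs(huge.mean) < 1e-10)
        tiny = vb.model_averaged_coefficients(y, X, post, vb.GPrior(1e-12))
        Xc = X - X.mean(axis=0)
        ols, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        assert np.allclose(tiny.mean, ols, rtol=1e-6)

    def test_pip_additivity_against_posterior_masses_k6(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 6))
        y = 0.4 + 0.03 * X[:, 2] + rng.normal(0, 0.03, 40)
        post = vb.enumerate_models(y, X, vb.default_g(40, 6))
        pips = vb.posterior_inclusion_probabilities(post)
        assert np.allclose(pips, brute_force_pips(post.posterior_probs, 6), atol=1e-10)

    def test_consistency_large_n_strong_effect(self):
        rng = np.random.default_rng(12)
        n = 500
        X = rng.normal(size=(n, 5))
        y = 0.45 - 0.04 * X[:, 3] + rng.normal(0, 0.02, n)
        post = vb.enumerate_models(y, X, vb.default_g(n, 5))
        pips = vb.posterior_inclusion_probabilities(post)
        assert pips[3] > 0.99
        assert np.all(np.delete(pips, 3) < 0.5)

    def test_rank_deficient_models_get_zero_probability(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=25)
        x2 = rng.normal(size=25)
        X = np.column_stack([x1, x2, x1 + x2])
        y = 0.4 + 0.05 * x1 + rng.normal(0, 0.02, 25)
        with pytest.warns(UserWarning, match="rank-deficient"):
            space = ModelSpace(X)
        assert space.n_rank_deficient == 1  # only the full {x1,x2,x1+x2} model
        post = vb.enumerate_models(y, X, vb.default_g(25, 3), space=space)
        assert post.posterior_probs[0b111] == 0.0
        assert post.posterior_probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_batch_and_single_voxel_paths_agree(self, small_regression):
        y, X = small_regression
        prior = vb.default_g(*X.shape)
        rng = np.random.default_rng(6)
        Y = np.column_stack([y, 0.45 + rng.normal(0, 0.03, len(y))])
        space = ModelSpace(X)
        pips_b, coefs_b = space.batch_pips_and_coefficients(Y, prior)
        for v in range(2):
            post = vb.enumerate_models(Y[:, v], X, prior, space=space)
            pips = vb.posterior_inclusion_probabilities(post)
            avg = vb.model_averaged_coefficients(Y[:, v], X, post, prior, space=space)
            assert np.allclose(pips_b[:, v], pips, atol=1e-12)
            assert np.allclose(coefs_b[:, v], avg.mean, atol=1e-14)
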