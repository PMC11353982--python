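import numpy as np
import pytest
from scipy import stats

from gwproc import (
    KernelSpec,
    WishartProcessConfig,
    construct_sigma,
    ema_mean,
    log_likelihood,
    predict_latent,
    predict_observations,
    sample_prior_state,
)
from gwproc.model import mvn_logpdf_sum, state_log_likelihood


class TestSamplePriorState:
    def test_deterministic_under_seed(self, small_config, small_grid):
        a = sample_prior_state(small_config, small_grid, np.random.default_rng(5))
        b = sample_prior_state(small_config, small_grid, np.random.default_rng(5))
        assert np.array_equal(a.F, b.F)
        assert np.array_equal(a.L, b.L)
        assert a.kernel.params == b.kernel.params

    def test_L_triangularity(self, rbf_spec):
        config = WishartProcessConfig(d=2, v=1, kernel=rbf_spec)
        st = sample_prior_state(config, np.array([0.0]), np.random.default_rng(0))
        assert st.L[0, 1] == 0.0
        assert st.L[1, 0] != 0.0

    def test_marginal_standard_normal_at_single_input(self, rbf_spec):
        # with k(x, x) = 1 each latent value is marginally N(0, 1)
        config = WishartProcessConfig(d=1, v=1, kernel=rbf_spec)
        rng = np.random.default_rng(99)
        draws = np.array(
            [
                sample_prior_state(config, np.array([0.3]), rng, jitter=0.0).F[0, 0, 0]
                for _ in range(10_000)
            ]
        )
        assert stats.kstest(draws, "norm").pvalue > 0.01


class TestConstructSigma:
    def test_scalar_outer_product(self):
        F = np.full((1, 1, 4), 3.0)
        assert np.allclose(construct_sigma(F, np.eye(1)), 9.0)

    def test_zero_scale_gives_zero(self, small_config, small_grid, rng):
        st = sample_prior_state(small_config, small_grid, rng)
        assert np.allclose(construct_sigma(st.F, np.zeros((2, 2))), 0.0)

    def test_invariant_to_latent_column_permutation(self, small_config, small_grid, rng):
        st = sample_prior_state(small_config, small_grid, rng)
        perm = rng.permutation(st.v)
        assert np.allclose(
            construct_sigma(st.F, st.L), construct_sigma(st.F[:, perm], st.L)
        )

    def test_marginal_matches_direct_wishart_moments(self, rng):
        # oracle: sum of outer products of v iid MVN(0, V) draws
        d, v, n_draws = 2, 3, 20_000
        L = np.array([[1.0, 0.0], [0.4, 0.8]])
        spec = KernelSpec("rbf", {"lengthscale": 0.35})
        config = WishartProcessConfig(d=d, v=v, kernel=spec)
        x = np.array([0.5])
        sigmas = np.empty((n_draws, d, d))
        for i in range(n_draws):
            F = rng.standard_normal((d, v, 1))  # k(x,x)=1: prior latents are N(0,1)
            sigmas[i] = construct_sigma(F, L)[0]
        mean = sigmas.mean(axis=0)
        expected = v * L @ L.T
        se = sigmas.std(axis=0, ddof=1) / np.sqrt(n_draws)
        assert np.all(np.abs(mean - expected) < 3 * se)


class TestLogLikelihood:
    def test_univariate_standard_normal(self):
        val = log_likelihood(
            np.zeros((1, 1)), np.ones((1, 1, 1)), jitter=0.0
        )
        assert val == pytest.approx(-0.9189385, abs=1e-6)

    def test_zero_residual_reduces_to_logdet_term(self, rng):
        n, d = 6, 3
        A = rng.standard_normal((n, d, d))
        Sigma = A @ np.swapaxes(A, 1, 2) + 0.5 * np.eye(d)
        Y = rng.standard_normal((n, d))
        val = log_likelihood(Y, Sigma, mean=Y, jitter=0.0)
        expected = -0.5 * sum(
            d * np.log(2 * np.pi) + np.linalg.slogdet(Sigma[i])[1] for i in range(n)
        )
        assert val == pytest.approx(expected, rel=1e-9)

    def test_doubling_variance_shifts_by_half_log_two(self):
        n = 5
        Y = np.zeros((n, 1))
        base = log_likelihood(Y, np.ones((n, 1, 1)), jitter=0.0)
        doubled = log_likelihood(Y, 2.0 * np.ones((n, 1, 1)), jitter=0.0)
        assert doubled - base == pytest.approx(-0.5 * np.log(2) * n, rel=1e-9)

    def test_invariant_to_joint_row_permutation(self, rng):
        n, d = 8, 2
        A = rng.standard_normal((n, d, d))
        Sigma = A @ np.swapaxes(A, 1, 2) + np.eye(d)
        Y = rng.standard_normal((n, d))
        perm = rng.permutation(n)
        assert log_likelihood(Y, Sigma) == pytest.approx(
            log_likelihood(Y[perm], Sigma[perm]), rel=1e-10
        )

    def test_closed_form_matches_scipy(self, rng):
        # d = 3 exercises the explicit adjugate path
        n, d = 7, 3
        A = rng.standard_normal((n, d, d))
        Sigma = A @ np.swapaxes(A, 1, 2) + np.eye(d)
        Y = rng.standard_normal((n, d))
        expected = sum(
            stats.multivariate_normal(np.zeros(d), Sigma[i]).logpdf(Y[i])
            for i in range(n)
        )
        assert mvn_logpdf_sum(Y, Sigma, jitter=0.0) == pytest.approx(expected, rel=1e-9)

    def test_indefinite_slice_returns_minus_inf(self):
        Sigma = -np.ones((1, 1, 1))
        assert mvn_logpdf_sum(np.ones((1, 1)), Sigma, jitter=0.0) == -np.inf

    @pytest.mark.parametrize("d,v,n", [(1, 1, 10), (2, 2, 40), (3, 4, 60), (4, 5, 20)])
    def test_compiled_path_agrees_with_reference(self, d, v, n, rng):
        # the samplers' fused likelihood kernel against the numpy reference
        from gwproc._fastpath import state_loglik

        F = rng.standard_normal((d, v, n))
        L = np.tril(rng.standard_normal((d, d)))
        resid = rng.standard_normal((n, d))
        fused = state_loglik(F, L, resid, 1e-6)
        reference = mvn_logpdf_sum(resid, construct_sigma(F, L), jitter=1e-6)
        assert fused == pytest.approx(reference, rel=1e-9)


class TestPredictLatent:
    def test_interpolates_training_values(self, rng):
        # short lengthscale keeps the Gram well conditioned, so the noiseless
        # conditional reproduces the stored latents up to solver error
        spec = KernelSpec("rbf", {"lengthscale": 0.08})
        config = WishartProcessConfig(d=2, v=3, kernel=spec)
        grid = np.linspace(0.0, 1.0, 8)
        st = sample_prior_state(config, grid, rng, jitter=1e-6, sample_theta=False)
        means, cov = predict_latent(st, grid, grid, jitter=1e-6)
        assert np.max(np.abs(means - st.F)) < 1e-4
        assert np.max(np.diag(cov)) <= 1.1e-6

    def test_reverts_to_prior_far_away(self, small_config, small_grid, rng):
        st = sample_prior_state(small_config, small_grid, rng, sample_theta=False)
        far = np.array([50.0])  # >> 20 lengthscales away
        means, cov = predict_latent(st, small_grid, far)
        assert np.max(np.abs(means)) < 1e-6
        assert cov[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_single_point_closed_form(self, rbf_spec, rng):
        config = WishartProcessConfig(d=1, v=1, kernel=rbf_spec)
        x = np.array([0.0])
        st = sample_prior_state(config, x, rng, jitter=1e-6, sample_theta=False)
        x_star = np.array([0.2])
        means, _ = predict_latent(st, x, x_star, jitter=1e-6)
        from gwproc import evaluate_kernel

        expected = evaluate_kernel(rbf_spec, 0.2, 0.0) * st.F[0, 0, 0] / (1 + 1e-6)
        assert means[0, 0, 0] == pytest.approx(expected, rel=1e-9)


class TestPredictObservations:
    def test_interpolation_of_training_sigma(self, rng):
        # tiny jitter: predictive draws at training inputs have ~sqrt(jitter) spread
        spec = KernelSpec("rbf", {"lengthscale": 0.08})
        config = WishartProcessConfig(d=2, v=3, kernel=spec)
        grid = np.linspace(0.0, 1.0, 8)
        st = sample_prior_state(config, grid, rng, jitter=1e-12, sample_theta=False)
        sub = grid[3:6]
        sigma_star, _ = predict_observations([st], grid, sub, rng, jitter=1e-12)
        target = construct_sigma(st.F, st.L)[3:6]
        assert np.max(np.abs(sigma_star[0] - target)) < 1e-4

    def test_empty_inputs_give_empty_outputs(self, small_config, small_grid, rng):
        st = sample_prior_state(small_config, small_grid, rng)
        sigma_star, y_star = predict_observations([st], small_grid, np.array([]), rng)
        assert sigma_star.shape[1] == 0 and y_star.shape[1] == 0

    def test_predictive_variance_matches_mean_sigma(self, rbf_spec):
        # d = v = 1, far input: Var(y*) = E[Sigma*] by the law of total variance
        config = WishartProcessConfig(d=1, v=1, kernel=rbf_spec)
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 10)
        states = [sample_prior_state(config, x, rng) for _ in range(400)]
        far = np.array([40.0])
        sigma_star, y_star = predict_observations(states, x, far, rng)
        assert y_star[:, 0, 0].var() == pytest.approx(
            sigma_star[:, 0, 0, 0].mean(), rel=0.25
        )


class TestEmaMean:
    def test_k1_lags_by_one(self, rng):
        Y = rng.standard_normal((8, 2))
        out = ema_mean(Y, k=1)
        assert np.allclose(out[1:], Y[:-1])
        assert np.allclose(out[0], 0.0)

    def test_constant_series_reproduced(self):
        Y = np.full((10, 1), 4.2)
        out = ema_mean(Y, k=2)
        # alpha = 2/3: weights 2/3 + 1/3 sum to one once history is full
        assert np.allclose(out[2:], 4.2)

    def test_weights_follow_alpha_decay(self, rng):
        Y = rng.standard_normal((6, 1))
        k = 4
        alpha = 2.0 / (k + 1)
        out = ema_mean(Y, k=k)
        i = 5
        expected = alpha * Y[i - 1, 0] + sum(
            (1 - alpha) ** m * Y[i - 1 - m, 0] for m in range(1, k)
        )
        assert out[i, 0] == pytest.approx(expected, rel=1e-12)

    def test_k_larger_than_series_truncates(self, rng):
        Y = rng.standard_normal((4, 1))
        out = ema_mean(Y, k=10)
        assert out.shape == Y.shape
        assert np.isfinite(out).all()

    def test_normalised_variant_averages_to_one(self):
        Y = np.full((9, 1), 2.0)
        out = ema_mean(Y, k=5, normalised=True)
        assert np.allclose(out[1:], 2.0)  # truncated history still sums to 1
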