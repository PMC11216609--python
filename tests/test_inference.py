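"""Variational inference: KL, reparameterization, ELBO, dynamics, training."""

import autograd
import autograd.numpy as anp
import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm

from dynetm import (
    ModelParameters,
    TrainConfig,
    VariationalState,
    dynamics_penalty,
    elbo_batch,
    infer_theta,
    kl_diag_gaussians,
    random_parameters,
    sample_corpus,
    train,
)
from dynetm.generative import softmax
from dynetm.inference import _kl_terms, theta_means


class TestKL:
    def test_identical_distributions_zero(self):
        mu = np.array([0.3, -1.2])
        sig = np.array([0.5, 2.0])
        assert kl_diag_gaussians(mu, sig, mu, sig) == pytest.approx(0.0, abs=1e-14)

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mu_q, mu_p = rng.standard_normal(2), rng.standard_normal(2)
            s_q, s_p = rng.uniform(0.1, 3, 2), rng.uniform(0.1, 3, 2)
            assert kl_diag_gaussians(mu_q, s_q, mu_p, s_p) >= 0

    def test_matches_numerical_quadrature(self):
        # 1-D case mu_q=1, s_q=1, mu_p=0, s_p=2 integrated directly
        def integrand(x):
            lq = norm.logpdf(x, 1.0, 1.0)
            return np.exp(lq) * (lq - norm.logpdf(x, 0.0, 2.0))

        expected, _ = quad(integrand, -30, 30)
        got = kl_diag_gaussians(1.0, 1.0, 0.0, 2.0)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            kl_diag_gaussians(0.0, 0.0, 0.0, 1.0)


class TestInferTheta:
    @pytest.fixture()
    def state(self):
        return VariationalState.init(V=12, K=3, n_labels=2, hidden=16, seed=0)

    def test_samples_on_simplex_and_deterministic(self, state):
        counts = np.arange(12, dtype=float)
        mu, sigma, samples = infer_theta(counts, state, np.zeros(3), n_samples=5, seed=4)
        assert samples.shape == (5, 3)
        assert np.allclose(samples.sum(axis=1), 1.0, atol=1e-8)
        _, _, again = infer_theta(counts, state, np.zeros(3), n_samples=5, seed=4)
        assert np.array_equal(samples, again)

    def test_zero_sigma_collapses_to_softmax_mu(self, state):
        counts = np.ones(12)
        mu, sigma, _ = infer_theta(counts, state, np.zeros(3), seed=0)
        state.theta_net["bs"] = np.full(3, -40.0)  # softplus -> ~0
        state.theta_net["Ws"] *= 0.0
        mu2, sigma2, samples = infer_theta(counts, state, np.zeros(3), n_samples=7, seed=1)
        assert sigma2.max() < 1e-5
        assert np.allclose(samples, softmax(mu2), atol=1e-4)

    def test_monte_carlo_moments(self, state):
        counts = np.linspace(1, 3, 12)
        mu, sigma, _ = infer_theta(counts, state, np.zeros(3), seed=0)
        rng = np.random.default_rng(11)
        draws = mu + sigma * rng.standard_normal((10_000, 3))
        se_mean = sigma / np.sqrt(10_000)
        assert (np.abs(draws.mean(axis=0) - mu) < 3 * se_mean).all()
        se_var = sigma ** 2 * np.sqrt(2.0 / (10_000 - 1))
        assert (np.abs(draws.var(axis=0) - sigma ** 2) < 3 * se_var).all()

    def test_empty_document_rejected(self, state):
        with pytest.raises(ValueError, match="empty document"):
            infer_theta(np.zeros(12), state, np.zeros(3))


class TestElbo:
    def test_k1_reconstruction_is_exact_loglik(self):
        # with one topic, theta == 1 and the reconstruction term is exact
        rng = np.random.default_rng(5)
        V = 6
        params = ModelParameters(rho=rng.standard_normal((3, V)),
                                 alpha=rng.standard_normal((1, 1, 3)),
                                 eta=np.zeros((1, 1)), eps=0.5)
        state = VariationalState.init(V=V, K=1, n_labels=2, hidden=8, seed=1)
        counts = rng.integers(0, 5, size=(2, V)).astype(float)
        counts[:, 0] += 1  # non-empty
        elbo, parts = elbo_batch(counts, 0, state, params, n_mc=3, seed=2)
        beta = params.beta()[0, 0]
        expected_recon = float(np.sum(counts * np.log(beta + 1e-10)))
        assert parts["recon"] == pytest.approx(expected_recon, rel=1e-9)
        kl = kl_diag_gaussians(parts["mu"].ravel(), parts["sigma"].ravel(),
                               np.zeros(2), np.full(2, 0.5))
        assert parts["kl"] == pytest.approx(kl, rel=1e-9)
        assert elbo == pytest.approx(parts["recon"] - parts["kl"])

    def test_sigma_zero_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(6)
        V, K = 3, 2
        params = ModelParameters(rho=rng.standard_normal((2, V)),
                                 alpha=rng.standard_normal((1, K, 2)),
                                 eta=rng.standard_normal((1, K)), eps=0.3)
        state = VariationalState.init(V=V, K=K, n_labels=2, hidden=8, seed=3)
        state.theta_net["Ws"] *= 0.0
        state.theta_net["bs"] = np.full(K, -40.0)
        counts = np.array([[2.0, 1.0, 0.0], [0.0, 3.0, 1.0]])
        elbo, parts = elbo_batch(counts, 0, state, params, n_mc=1, seed=7)
        # oracle: theta = softmax(mu); recon and KL from explicit formulas
        mu, sigma = parts["mu"], parts["sigma"]
        theta = softmax(mu, axis=1)
        beta = params.beta()[0]
        recon = float(np.sum(counts * np.log(theta @ beta + 1e-10)))
        kl = float(sum(
            kl_diag_gaussians(mu[i], sigma[i], params.eta[0], np.full(K, 0.3))
            for i in range(2)))
        assert elbo == pytest.approx(recon - kl, rel=1e-6)

    def test_scale_factor_applied(self):
        rng = np.random.default_rng(7)
        params = random_parameters(K=2, V=5, L=3, T=1, seed=0)
        state = VariationalState.init(V=5, K=2, n_labels=2, hidden=8, seed=0)
        counts = rng.integers(1, 4, size=(3, 5)).astype(float)
        e1, _ = elbo_batch(counts, 0, state, params, seed=1, scale=1.0)
        e2, _ = elbo_batch(counts, 0, state, params, seed=1, scale=2.5)
        assert e2 == pytest.approx(2.5 * e1, rel=1e-12)

    def test_unknown_slice_rejected(self):
        params = random_parameters(K=2, V=5, L=3, T=1, seed=0)
        state = VariationalState.init(V=5, K=2, n_labels=2, hidden=8, seed=0)
        with pytest.raises(ValueError, match="slice"):
            elbo_batch(np.ones((1, 5)), 3, state, params)


class TestDynamicsPenalty:
    def test_zero_trajectories(self):
        p = ModelParameters(rho=np.zeros((2, 4)), alpha=np.zeros((3, 2, 2)),
                            eta=np.zeros((3, 2)), eps=0.1, delta=0.1, gamma=0.1)
        assert dynamics_penalty(p) == 0.0

    def test_quadratic_in_increment(self):
        base = np.zeros((2, 1, 1))
        base[1, 0, 0] = 1.0
        doubled = base * 2
        pen1 = dynamics_penalty(base, np.zeros((2, 1)), gamma=0.5, delta=0.5)
        pen2 = dynamics_penalty(doubled, np.zeros((2, 1)), gamma=0.5, delta=0.5)
        assert pen2 == pytest.approx(4 * pen1, rel=1e-12)

    def test_matches_gaussian_log_density(self):
        # T=3, K=1, L=1 trajectory scored against explicit normal log-pdfs
        alpha = np.array([0.4, 0.9, 0.7]).reshape(3, 1, 1)
        eta = np.array([-0.2, 0.1, 0.3]).reshape(3, 1)
        gamma, delta = 0.3, 0.6
        pen = dynamics_penalty(alpha, eta, gamma=gamma, delta=delta)
        logp = (norm.logpdf(alpha[0], 0, 1) + norm.logpdf(eta[0], 0, 1)
                + norm.logpdf(alpha[1], alpha[0], gamma)
                + norm.logpdf(alpha[2], alpha[1], gamma)
                + norm.logpdf(eta[1], eta[0], delta)
                + norm.logpdf(eta[2], eta[1], delta)).sum()
        consts = (2 * np.log(np.sqrt(2 * np.pi))
                  + 2 * np.log(np.sqrt(2 * np.pi) * gamma)
                  + 2 * np.log(np.sqrt(2 * np.pi) * delta))
        assert pen == pytest.approx(-logp - consts, rel=1e-9)


class TestGradients:
    def test_autograd_matches_finite_differences(self):
        """ELBO gradients w.r.t. mu and sigma on a 2-doc, V=3, K=2 instance."""
        rng = np.random.default_rng(8)
        counts = np.array([[2.0, 0.0, 1.0], [1.0, 3.0, 0.0]])
        beta = rng.dirichlet(np.ones(3), size=2)
        eta = np.array([0.2, -0.1])
        eps = 0.5
        noise = rng.standard_normal((1, 2, 2))

        def elbo_fn(mu, sigma):
            theta = softmax(mu + sigma * noise[0], axis=1)
            recon = anp.sum(counts * anp.log(anp.dot(theta, beta) + 1e-10))
            kl = anp.sum(_kl_terms(mu, sigma, eta, eps))
            return recon - kl

        mu0 = rng.standard_normal((2, 2))
        sig0 = rng.uniform(0.3, 1.0, size=(2, 2))
        g_mu = autograd.grad(elbo_fn, 0)(mu0, sig0)
        g_sig = autograd.grad(elbo_fn, 1)(mu0, sig0)
        h = 1e-6
        for g, arg in ((g_mu, 0), (g_sig, 1)):
            x0 = [mu0.copy(), sig0.copy()]
            for idx in np.ndindex(2, 2):
                xp = [mu0.copy(), sig0.copy()]
                xm = [mu0.copy(), sig0.copy()]
                xp[arg][idx] += h
                xm[arg][idx] -= h
                fd = (elbo_fn(*xp) - elbo_fn(*xm)) / (2 * h)
                assert abs(g[idx] - fd) <= 1e-4 * max(1.0, abs(fd))


class TestTraining:
    def test_elbo_improves(self):
        params = random_parameters(K=3, V=40, L=6, T=2, eps=1.0, seed=10)
        corpus, _ = sample_corpus(params, [60, 60], tokens_per_doc=30, seed=10)
        cfg = TrainConfig(K=3, L=6, epochs=50, batch_size=128, seed=0, eps=1.0,
                          hidden=32)
        _, _, log = train(corpus, cfg, init_rho=params.rho)
        assert log[49]["elbo"] > log[0]["elbo"]

    def test_reproducible_bit_for_bit(self):
        params = random_parameters(K=2, V=25, L=4, T=2, eps=1.0, seed=11)
        corpus, _ = sample_corpus(params, [30, 30], tokens_per_doc=20, seed=11)
        cfg = TrainConfig(K=2, L=4, epochs=8, batch_size=64, seed=3, eps=1.0,
                          hidden=16)
        mp1, vs1, log1 = train(corpus, cfg)
        mp2, vs2, log2 = train(corpus, cfg)
        assert np.array_equal(mp1.alpha, mp2.alpha)
        assert np.array_equal(mp1.rho, mp2.rho)
        assert np.array_equal(mp1.eta, mp2.eta)
        for k in vs1.theta_net:
            assert np.array_equal(vs1.theta_net[k], vs2.theta_net[k])
        assert log1 == log2

    def test_divergence_reported_with_location(self):
        params = random_parameters(K=2, V=10, L=3, T=1, eps=1.0, seed=12)
        corpus, _ = sample_corpus(params, [20], tokens_per_doc=10, seed=12)
        corpus.counts[0] = corpus.counts[0].astype(float)
        corpus.counts[0][0, 0] = np.nan  # corrupted input -> non-finite loss
        cfg = TrainConfig(K=2, L=3, epochs=3, batch_size=32, seed=0, eps=1.0,
                          hidden=8)
        with pytest.raises(RuntimeError, match="epoch 0"):
            train(corpus, cfg)

    def test_amortized_eta_posterior_smoke(self):
        params = random_parameters(K=2, V=20, L=4, T=3, eps=1.0, seed=13)
        corpus, _ = sample_corpus(params, [25, 25, 25], tokens_per_doc=15, seed=13)
        cfg = TrainConfig(K=2, L=4, epochs=4, batch_size=64, seed=1, eps=1.0,
                          hidden=16, eta_posterior="amortized")
        mp, vs, log = train(corpus, cfg)
        assert vs.eta_net is not None
        assert mp.eta.shape == (3, 2)
        assert np.isfinite(log[-1]["elbo"])

    def test_recovers_simulated_topics(self):
        """Trained topic-word distributions match the simulating truth.

        Simulation uses a document-level topic-proportion spread (logit std
        1.0) so the decomposition is identifiable from the data.
        """
        params = random_parameters(K=3, V=200, L=16, T=4, eps=1.0, delta=0.01,
                                   gamma=0.01, seed=1)
        corpus, truth = sample_corpus(params, [500] * 4, tokens_per_doc=60, seed=1)
        cfg = TrainConfig(K=3, L=16, epochs=200, learning_rate=3e-3, seed=1,
                          eps=1.0, delta=0.01, gamma=0.01)
        mp, vs, _ = train(corpus, cfg, init_rho=params.rho)
        Bt, Bl = params.beta().mean(axis=0), mp.beta().mean(axis=0)
        C = np.array([[Bt[i] @ Bl[j] / (np.linalg.norm(Bt[i]) * np.linalg.norm(Bl[j]))
                       for j in range(3)] for i in range(3)])
        ri, cj = linear_sum_assignment(-C)
        assert C[ri, cj].mean() >= 0.9
        th_true = truth.theta_matrix()
        th_learn = np.vstack([
            theta_means(corpus.dense_counts(t), vs, mp.eta[t]) for t in range(4)
        ])[:, cj]
        cos = np.sum(th_true * th_learn, axis=1) / (
            np.linalg.norm(th_true, axis=1) * np.linalg.norm(th_learn, axis=1))
        assert cos.mean() >= 0.8
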