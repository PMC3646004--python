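"""Sampler correctness: exact conditionals, prior recovery, quadrature oracles."""

import arviz as az
import numpy as np
import pytest
from scipy import stats
from scipy.special import gamma as gamma_fn

from statewalk.fit import (
    ChainSamples,
    MCMCConfig,
    ModelData,
    PriorSpec,
    init_chain,
    label_probabilities,
    run_chain,
    split_rhat,
    update_labels,
    update_state_params,
    update_weights,
)
from statewalk.preprocess import StepSeries


def make_steps(r, phi):
    r = np.asarray(r, dtype=float)
    phi = np.asarray(phi, dtype=float)
    return StepSeries(t=np.arange(len(r), dtype=float), r=r, phi=phi, interval=1.0)


def make_state(a, b, mu, rho, w, z):
    return {
        "a": np.asarray(a, float), "b": np.asarray(b, float),
        "mu": np.asarray(mu, float), "rho": np.asarray(rho, float),
        "w": np.asarray(w, float), "z": np.asarray(z, int),
    }


EMPTY = make_steps([], [])


def mcse(samples):
    """Monte-Carlo SE of a posterior mean, from the effective sample size."""
    ess = float(az.ess(np.asarray(samples)))
    return np.std(samples) / np.sqrt(max(ess, 1.0))


class TestInitChain:
    def test_single_state(self):
        steps = make_steps([0.5, 1.0, 1.5, 0.7, 0.9], [0.1] * 5)
        st0 = init_chain(steps, 1, PriorSpec(), np.random.default_rng(0))
        np.testing.assert_array_equal(st0["z"], 0)
        np.testing.assert_array_equal(st0["w"], [1.0])

    def test_deterministic_given_seed(self):
        steps = make_steps(np.linspace(0.2, 2.0, 12), [0.0] * 12)
        s1 = init_chain(steps, 2, PriorSpec(), np.random.default_rng(9))
        s2 = init_chain(steps, 2, PriorSpec(), np.random.default_rng(9))
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_bimodal_rates_give_distinct_means(self):
        rng = np.random.default_rng(1)
        r = np.concatenate([rng.normal(0.5, 0.05, 50), rng.normal(3.0, 0.2, 50)])
        steps = make_steps(np.abs(r), np.zeros(100))
        st0 = init_chain(steps, 2, PriorSpec(), np.random.default_rng(2))
        means = st0["b"] * gamma_fn(1 + 1 / st0["a"])
        assert abs(means[0] - means[1]) > 0.5

    def test_too_little_data(self):
        steps = make_steps([0.5, 1.0], [0.1, 0.2])
        with pytest.raises(ValueError, match="too little data"):
            init_chain(steps, 2, PriorSpec(), np.random.default_rng(0))


class TestLabelConditionals:
    def test_identical_states_conditional_equals_weights(self):
        steps = make_steps([0.5, 1.2, 0.8], [0.1, -0.4, 2.0])
        state = make_state([1.5, 1.5], [1.0, 1.0], [0.0, 0.0], [0.3, 0.3],
                           [0.3, 0.7], [0, 0, 0])
        p = label_probabilities(state, ModelData(steps))
        np.testing.assert_allclose(p, np.tile([0.3, 0.7], (3, 1)), atol=1e-12)

    def test_extreme_likelihood_ratio(self):
        # state 2's Weibull mean sits far from the observed rate: density
        # ratio f1/f2 >> 1, so with equal weights P(z=1) ~ 1
        steps = make_steps([1.0], [np.nan])
        state = make_state([3.0, 3.0], [1.0, 30.0], [0.0, 0.0], [0.0, 0.0],
                           [0.5, 0.5], [0])
        p = label_probabilities(state, ModelData(steps))
        ratio = np.exp(
            stats.weibull_min.logpdf(1.0, 3.0, scale=1.0)
            - stats.weibull_min.logpdf(1.0, 3.0, scale=30.0)
        )
        assert p[0, 0] == pytest.approx(ratio / (1.0 + ratio), rel=1e-9)
        assert p[0, 0] > 0.999

    def test_draws_match_enumeration_tv(self):
        """Joint label draws on a 4-point dataset match the enumerated product
        of exact full conditionals (TV < 0.01 at 1e5 draws)."""
        steps = make_steps([0.4, 1.0, 1.8, 0.7], [0.2, -2.9, 0.1, 1.2])
        state = make_state([1.2, 2.5], [0.6, 1.8], [np.pi, 0.0], [0.5, 0.4],
                           [0.45, 0.55], [0, 0, 0, 0])
        data = ModelData(steps)
        p = label_probabilities(state, data)  # (4, 2) exact conditionals
        # exact joint over the 16 configurations (draws are independent per point)
        exact = np.ones(16)
        for cfg_idx in range(16):
            bits = [(cfg_idx >> i) & 1 for i in range(4)]
            exact[cfg_idx] = np.prod([p[t, bits[t]] for t in range(4)])
        rng = np.random.default_rng(2024)
        n = 10**5
        counts = np.zeros(16)
        for _ in range(n):
            z = update_labels(state, data, rng)
            counts[int(np.dot(z, [1, 2, 4, 8]))] += 1
        tv = 0.5 * np.abs(counts / n - exact).sum()
        assert tv < 0.01

    def test_single_point_frequencies_within_3_sigma(self):
        steps = make_steps([0.9], [1.5])
        state = make_state([1.1, 3.0], [0.7, 2.0], [0.3, -0.3], [0.6, 0.2],
                           [0.25, 0.75], [0])
        data = ModelData(steps)
        p_exact = label_probabilities(state, data)[0, 0]
        rng = np.random.default_rng(7)
        n = 10**5
        hits = sum(int(update_labels(state, data, rng)[0] == 0) for _ in range(n))
        se = np.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(hits / n - p_exact) < 3 * se


class TestWeightConditional:
    def test_single_state(self):
        state = make_state([1.0], [1.0], [0.0], [0.1], [1.0], [0, 0, 0])
        np.testing.assert_array_equal(update_weights(state, np.random.default_rng(0)), [1.0])

    def test_dirichlet_mean(self):
        # counts (10, 0) -> w ~ Dirichlet(11, 1), E[w1] = 11/12
        state = make_state([1, 1], [1, 1], [0, 0], [0.1, 0.1], [0.5, 0.5], [0] * 10)
        rng = np.random.default_rng(3)
        draws = np.array([update_weights(state, rng)[0] for _ in range(10_000)])
        exact_mean = 11.0 / 12.0
        exact_sd = np.sqrt(11.0 / (12.0**2 * 13.0))
        assert abs(draws.mean() - exact_mean) < 3 * exact_sd / 100.0

    def test_sums_to_one(self):
        state = make_state([1, 1, 1], [1, 1, 1], [0, 0, 0], [0.1] * 3,
                           [1 / 3] * 3, [0, 1, 2, 1])
        rng = np.random.default_rng(4)
        for _ in range(20):
            assert update_weights(state, rng).sum() == pytest.approx(1.0)


class TestParamUpdates:
    def test_zero_proposal_sd_keeps_values(self):
        steps = make_steps([0.5, 1.0, 0.7], [0.1, 0.2, -0.2])
        state = make_state([1.4], [0.9], [0.3], [0.35], [1.0], [0, 0, 0])
        before = {k: state[k].copy() for k in ("a", "b", "mu", "rho")}
        sd = {"a": 0.0, "b": 0.0, "mu": 0.0, "rho": 0.0}
        update_state_params(state, ModelData(steps), PriorSpec(),
                            np.random.default_rng(0), sd)
        for k, v in before.items():
            np.testing.assert_allclose(state[k], v, atol=1e-14)

    def test_prior_only_recovery(self):
        """With no data the Metropolis blocks sample the prior: Gamma(0.3, 0.01)
        for a and b (mean 30), uniform for rho on (0, rho_max)."""
        prior = PriorSpec()
        state = make_state([30.0], [30.0], [0.0], [0.5], [1.0], [])
        data = ModelData(EMPTY)
        rng = np.random.default_rng(11)
        sd = {"a": 3.0, "b": 3.0, "mu": 2.0, "rho": 0.3}
        n = 30_000
        a_s = np.empty(n)
        b_s = np.empty(n)
        rho_s = np.empty(n)
        for i in range(n):
            update_state_params(state, data, prior, rng, sd)
            a_s[i], b_s[i], rho_s[i] = state["a"][0], state["b"][0], state["rho"][0]
        for s in (a_s, b_s):
            assert abs(s.mean() - 30.0) < 3 * mcse(s)
            # distribution-shape check at a fixed quantile, robust to tail noise
            p1 = stats.gamma.cdf(1.0, prior.gamma_shape, scale=1 / prior.gamma_rate)
            assert abs(np.mean(s < 1.0) - p1) < 3 * mcse((s < 1.0).astype(float))
        assert abs(rho_s.mean() - prior.rho_max / 2) < 3 * mcse(rho_s)
        assert abs(np.mean(rho_s < prior.rho_max / 4) - 0.25) < 3 * mcse(
            (rho_s < prior.rho_max / 4).astype(float)
        )

    def test_single_state_posterior_matches_grid_quadrature(self):
        """MCMC posterior means on 5 points match dense-grid quadrature.

        With one state the posterior factorises into (a, b) x (mu, rho), so
        two 2-D grids integrate it exactly (up to discretisation).
        """
        r = np.array([0.3, 0.8, 1.4, 0.6, 1.0])
        phi = np.array([0.2, -0.5, 3.0, 0.9, -0.1])
        steps = make_steps(r, phi)
        prior = PriorSpec()

        # --- (a, b) grid posterior -------------------------------------
        A = np.linspace(0.02, 20.0, 900)
        B = np.linspace(0.02, 15.0, 900)
        la = (prior.gamma_shape - 1) * np.log(A) - prior.gamma_rate * A
        lb = (prior.gamma_shape - 1) * np.log(B) - prior.gamma_rate * B
        ll = np.zeros((A.size, B.size))
        for ri in r:
            ll += (
                np.log(A)[:, None]
                - np.log(B)[None, :]
                + (A[:, None] - 1) * (np.log(ri) - np.log(B)[None, :])
                - (ri / B[None, :]) ** A[:, None]
            )
        post_ab = np.exp(ll + la[:, None] + lb[None, :] - (ll + la[:, None] + lb[None, :]).max())
        post_ab /= post_ab.sum()
        grid_a = float((post_ab.sum(axis=1) * A).sum())
        grid_b = float((post_ab.sum(axis=0) * B).sum())

        # --- (mu, rho) grid posterior ----------------------------------
        MU = np.linspace(-np.pi, np.pi, 721, endpoint=False) + np.pi / 721
        RHO = np.linspace(1e-4, prior.rho_max - 1e-4, 600)
        llw = np.zeros((MU.size, RHO.size))
        for pi_ in phi:
            llw += np.log(1 - RHO**2)[None, :] - np.log(
                1 + RHO[None, :] ** 2 - 2 * RHO[None, :] * np.cos(pi_ - MU[:, None])
            )
        post_mr = np.exp(llw - llw.max())
        post_mr /= post_mr.sum()
        grid_mu = float((post_mr.sum(axis=1) * MU).sum())
        grid_rho = float((post_mr.sum(axis=0) * RHO).sum())

        chain = run_chain(
            steps, 1, prior,
            MCMCConfig(n_iter=40_000, burn_in=2_000, thin=10, seed=5),
        )
        for samples, target, scale in (
            (chain.a[:, 0], grid_a, grid_a),
            (chain.b[:, 0], grid_b, grid_b),
            (chain.mu[:, 0], grid_mu, np.pi),
            (chain.rho[:, 0], grid_rho, 1.0),
        ):
            tol = 3 * mcse(samples) + 0.02 * scale  # quadrature discretisation margin
            assert abs(samples.mean() - target) < tol


class TestRunChain:
    def test_kept_sample_count(self):
        steps = make_steps(np.linspace(0.2, 2.0, 12), np.zeros(12))
        chain = run_chain(steps, 1, PriorSpec(),
                          MCMCConfig(n_iter=1000, burn_in=100, thin=10, seed=0))
        assert chain.n_samples == 100

    def test_bit_identical_given_seed(self):
        steps = make_steps(np.linspace(0.2, 2.0, 12), np.zeros(12))
        cfg = MCMCConfig(n_iter=500, burn_in=50, thin=5, seed=42)
        c1 = run_chain(steps, 2, PriorSpec(), cfg)
        c2 = run_chain(steps, 2, PriorSpec(), cfg)
        for k in ("a", "b", "mu", "rho", "w", "z"):
            np.testing.assert_array_equal(getattr(c1, k), getattr(c2, k))

    def test_rho_within_bounds_and_labels_in_range(self, chain_f1):
        assert np.all(chain_f1.rho >= 0) and np.all(chain_f1.rho <= chain_f1.rho_max)
        assert chain_f1.z.min() >= 0 and chain_f1.z.max() < chain_f1.n_states

    def test_split_rhat_converged(self, chain_f1):
        rhats = split_rhat(chain_f1)
        for name in ("a", "b", "rho"):
            assert np.all(rhats[name] < 1.1), f"{name}: {rhats[name]}"

    def test_archive_round_trip(self, tmp_path, chain_f1):
        p = tmp_path / "chain.npz"
        chain_f1.save(p)
        back = ChainSamples.load(p)
        np.testing.assert_array_equal(back.a, chain_f1.a)
        np.testing.assert_array_equal(back.z, chain_f1.z)
        assert back.config == chain_f1.config
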