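"""Gibbs sampler components: prior, likelihoods, conditionals, updates."""

import math

import numpy as np
import pytest
from scipy import stats

import lgibp.sampler as sm
from lgibp.sampler import (Hyperparameters, SamplerConfig, SamplerState,
                           as_model_data, collapsed_log_marginal,
                           conditional_inclusion_probability, harmonic_number,
                           ibp_log_prior, prior_draw, resample_alpha,
                           run_sampler, sample_weights,
                           continuous_feature_values)


class TestPriorDraw:
    def test_alpha_zero_gives_no_columns(self):
        for n in (1, 7):
            assert prior_draw(n, 0.0, seed=1).shape == (n, 0)

    def test_first_customer_poisson_mean(self):
        # n=1: column count is Poisson(alpha)
        counts = [prior_draw(1, 2.0, seed=s).shape[1] for s in range(2000)]
        se = math.sqrt(2.0 / 2000)
        assert abs(np.mean(counts) - 2.0) < 3 * se
        var_se = 3 * math.sqrt(2 * 2.0 ** 2 / 2000)  # rough SE of variance
        assert abs(np.var(counts) - 2.0) < var_se + 0.3

    def test_total_columns_match_alpha_harmonic(self):
        n, alpha, reps = 30, 1.5, 1500
        counts = [prior_draw(n, alpha, seed=s).shape[1]
                  for s in range(reps)]
        expect = alpha * harmonic_number(n)
        se = math.sqrt(expect / reps)  # K is Poisson(alpha * H_n)
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_no_empty_columns(self):
        z = prior_draw(40, 3.0, seed=5)
        assert (z.sum(axis=0) >= 1).all()


class TestIbpLogPrior:
    def test_rejects_empty_columns(self):
        with pytest.raises(ValueError):
            ibp_log_prior(np.zeros((3, 1), dtype=int), 1.0)

    def test_k0_probability(self):
        # P(K=0) = exp(-alpha * H_n)
        assert ibp_log_prior(np.zeros((4, 0)), 1.5) == pytest.approx(
            -1.5 * harmonic_number(4))

    def test_matches_simulation_frequency(self):
        # frequency of the single-column all-ones class for n=2 vs formula
        n, alpha, reps = 2, 1.0, 4000
        target = np.array([[1], [1]])
        hits = sum(
            1 for s in range(reps)
            if (lambda z: z.shape[1] == 1 and (z == target).all())(
                prior_draw(n, alpha, seed=s)))
        expect = math.exp(ibp_log_prior(target, alpha))
        se = math.sqrt(expect * (1 - expect) / reps)
        assert abs(hits / reps - expect) < 3.5 * se


class TestCollapsedMarginal:
    def test_no_feature_limit_is_iid_normal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 3))
        ll = collapsed_log_marginal(x, np.zeros((5, 0)), 0.7, 1.0)
        expect = stats.norm.logpdf(x, scale=0.7).sum()
        assert ll == pytest.approx(expect)

    def test_joint_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 2))
        z = (rng.random((6, 2)) < 0.5).astype(float)
        z[0, 0] = 1  # avoid empty columns irrelevant here
        perm = rng.permutation(6)
        a = collapsed_log_marginal(x, z, 0.8, 1.2)
        b = collapsed_log_marginal(x[perm], z[perm], 0.8, 1.2)
        assert a == pytest.approx(b)

    def test_masked_cells_rejected(self):
        x = np.ones((3, 2))
        mask = np.ones((3, 2), bool)
        mask[0, 0] = False
        with pytest.raises(ValueError, match="complete"):
            collapsed_log_marginal((x, mask), np.ones((3, 1)), 1.0, 1.0)

    def test_against_monte_carlo_integration(self):
        """N=2, D=1 marginal matches brute-force integration over the
        weight prior."""
        x = np.array([[1.0], [-1.0]])
        z = np.array([[1.0], [1.0]])
        ll = collapsed_log_marginal(x, z, 1.0, 1.0)
        rng = np.random.default_rng(42)
        draws = rng.normal(0.0, 1.0, size=1_000_000)
        lik = np.exp(stats.norm.logpdf(x[0, 0], loc=draws)
                     + stats.norm.logpdf(x[1, 0], loc=draws))
        mc = lik.mean()
        mc_se = lik.std(ddof=1) / math.sqrt(len(lik))
        assert abs(math.exp(ll) - mc) < 3 * mc_se


def _make_state(z, a, sigma_x=1.0, sigma_a=1.0, seed=0):
    return SamplerState(z=np.asarray(z, dtype=np.int8),
                        a=np.asarray(a, float),
                        hypers=Hyperparameters(alpha=1.0, sigma_x=sigma_x,
                                               sigma_a=sigma_a),
                        rng=np.random.default_rng(seed))


class TestConditionalInclusion:
    def test_flat_likelihood_reduces_to_prior(self):
        # zero weights make L1 = L0, so probability is m_{-i,k} / N
        z = np.array([[1], [1], [1], [0], [0], [0]])
        a = np.zeros((1, 2))
        state = _make_state(z, a)
        x = np.zeros((6, 2))
        p = conditional_inclusion_probability(state, x, i=5, k=0)
        assert p == pytest.approx(3 / 6)

    def test_likelihood_dominated_limit(self):
        z = np.array([[1], [1], [0]])
        a = np.array([[5.0, 5.0]])
        x = np.array([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        state = _make_state(z, a, sigma_x=0.1)
        p = conditional_inclusion_probability(state, x, i=2, k=0)
        assert p > 0.999999

    def test_fully_masked_row_gives_prior_exactly(self):
        z = np.array([[1], [1], [0], [0]])
        a = np.array([[2.0, -1.0]])
        x = np.ones((4, 2))
        mask = np.ones((4, 2), bool)
        mask[3] = False
        state = _make_state(z, a)
        p = conditional_inclusion_probability(state, (x, mask), i=3, k=0)
        assert p == pytest.approx(2 / 4)

    def test_popularity_zero_rejected(self):
        state = _make_state(np.array([[1], [0]]), np.zeros((1, 1)))
        with pytest.raises(ValueError, match="new-feature"):
            conditional_inclusion_probability(state, np.zeros((2, 1)),
                                              i=0, k=0)


class TestSampleWeights:
    def test_conjugate_update_single_feature(self):
        """x = (1,1,1,1), z all ones, unit scales: posterior mean 4/5,
        variance 1/5."""
        z = np.ones((4, 1))
        data = as_model_data(np.ones((4, 1)))
        draws = [sample_weights(z, data, 1.0, 1.0,
                                np.random.default_rng(s))[0, 0]
                 for s in range(4000)]
        assert np.mean(draws) == pytest.approx(0.8, abs=4 * math.sqrt(
            0.2 / 4000))
        assert np.var(draws) == pytest.approx(0.2, rel=0.15)

    def test_fully_masked_measure_draws_from_prior(self):
        z = np.ones((5, 1))
        x = np.full((5, 1), 100.0)
        mask = np.zeros((5, 1), bool)
        data = as_model_data((x, mask))
        draws = [sample_weights(z, data, 1.0, 2.0,
                                np.random.default_rng(s))[0, 0]
                 for s in range(3000)]
        assert abs(np.mean(draws)) < 4 * 2.0 / math.sqrt(3000)
        assert np.std(draws) == pytest.approx(2.0, rel=0.1)

    def test_noiseless_limit_recovers_least_squares(self):
        rng = np.random.default_rng(3)
        z = (rng.random((30, 2)) < 0.5).astype(float)
        z[:2] = [[1, 0], [0, 1]]
        a_true = rng.normal(size=(2, 3))
        x = z @ a_true
        data = as_model_data(x)
        a = sample_weights(z, data, 1e-6, 10.0, np.random.default_rng(0))
        np.testing.assert_allclose(a, a_true, atol=1e-4)

    def test_masked_equals_deleted(self):
        """Masking a cell is algebraically identical to deleting that
        cell's likelihood term from the weight full conditional."""
        rng = np.random.default_rng(9)
        for trial in range(100):
            n, k = rng.integers(4, 10), rng.integers(1, 4)
            z = (rng.random((n, k)) < 0.5).astype(float)
            x = rng.normal(size=(n, 1))
            mask = rng.random((n, 1)) > 0.3
            if not mask.any():
                mask[0, 0] = True
            sx, sa = 0.7, 1.3
            # masked-cell route
            zf = z[mask[:, 0]]
            xv = x[mask[:, 0], 0]
            prec_mask = zf.T @ zf / sx ** 2 + np.eye(k) / sa ** 2
            mean_mask = np.linalg.solve(prec_mask, zf.T @ xv / sx ** 2)
            # deleted-row route
            z_del = np.delete(z, np.flatnonzero(~mask[:, 0]), axis=0)
            x_del = np.delete(x[:, 0], np.flatnonzero(~mask[:, 0]))
            prec_del = z_del.T @ z_del / sx ** 2 + np.eye(k) / sa ** 2
            mean_del = np.linalg.solve(prec_del, z_del.T @ x_del / sx ** 2)
            np.testing.assert_allclose(prec_mask, prec_del, atol=1e-12)
            np.testing.assert_allclose(mean_mask, mean_del, atol=1e-12)


class TestHyperUpdates:
    def test_alpha_conjugate_k0(self):
        # shape 1, rate 1, K=0, n=1: posterior Gamma(1, 2), mean 1/2
        draws = [resample_alpha(0, 1, 1.0, 1.0, np.random.default_rng(s))
                 for s in range(4000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.05)

    def test_alpha_posterior_mean_monotone_in_k(self):
        means = [(1.0 + k) / (1.0 + harmonic_number(20)) for k in range(5)]
        assert all(m2 > m1 for m1, m2 in zip(means, means[1:]))

    def test_zero_proposal_scale_keeps_scales(self):
        rng = np.random.default_rng(0)
        z = np.ones((4, 1), dtype=np.int8)
        state = SamplerState(
            z=z, a=np.ones((1, 2)),
            hypers=Hyperparameters(sigma_proposal_scale=0.0), rng=rng)
        data = as_model_data(np.ones((4, 2)))
        sx, sa = sm.resample_noise_scales(state, data)
        assert (sx, sa) == (1.0, 1.0)

    def test_sigma_x_recovery_with_fixed_truth(self):
        """With Z, A fixed at truth, the sigma_x chain mean approaches the
        planted noise SD."""
        rng = np.random.default_rng(7)
        n, d = 80, 10
        z = (rng.random((n, 3)) < 0.4).astype(np.int8)
        a = rng.normal(size=(3, d))
        x = z @ a + rng.normal(0, 0.5, size=(n, d))
        data = as_model_data(x)
        state = SamplerState(z=z, a=a, hypers=Hyperparameters(),
                             rng=np.random.default_rng(1))
        chain = []
        for _ in range(400):
            state.hypers.sigma_x, state.hypers.sigma_a = \
                sm.resample_noise_scales(state, data)
            chain.append(state.hypers.sigma_x)
        assert np.mean(chain[100:]) == pytest.approx(0.5, rel=0.05)


class TestRunSampler:
    def test_same_seed_identical_traces(self, standardized):
        cfg = SamplerConfig(sweeps=8, seed=123)
        _, t1 = run_sampler(standardized, cfg)
        _, t2 = run_sampler(standardized, cfg)
        assert t1.equals(t2)

    def test_sweep_count_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(sweeps=0)

    def test_trace_k_matches_state(self, standardized):
        state, trace = run_sampler(standardized,
                                   SamplerConfig(sweeps=6, seed=1))
        assert trace["k"].iloc[-1] == state.k
        assert (state.z.sum(axis=0) >= 1).all()  # no empty columns survive

    def test_zero_alpha_empty_data_stays_empty(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        cfg = SamplerConfig(sweeps=5, seed=2, alpha_init=1e-12,
                            resample_alpha=False)
        state, trace = run_sampler(x, cfg)
        assert state.k == 0 and (trace["k"] == 0).all()

    def test_values_are_probabilities(self, standardized):
        state, _ = run_sampler(standardized, SamplerConfig(sweeps=10,
                                                           seed=3))
        vals = continuous_feature_values(state, standardized)
        assert vals.shape == (standardized.n_participants, state.k)
        assert (vals >= 0).all() and (vals <= 1).all()

    def test_fully_masked_row_gets_prior_values(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 4))
        mask = np.ones((20, 4), bool)
        mask[0] = False
        state, _ = run_sampler((x, mask), SamplerConfig(sweeps=10, seed=5))
        if state.k:
            vals = continuous_feature_values(state, (x, mask))
            m_minus = state.z.sum(axis=0) - state.z[0]
            np.testing.assert_allclose(vals[0], m_minus / 20)
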