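"""HMM inference: exhaustive-path oracles, EM behaviour, ordering, dwell times."""

import itertools

import numpy as np
import pytest
import scipy.stats

from twinstates import (
    GaussianHMM,
    default_base_model,
    dwell_times,
    fit_hmm,
    forward_backward,
    order_states,
    simulate_subject,
    standardize_concatenate,
    viterbi,
)
from twinstates.hmm import _em_once, _kmeans_init


def _brute_loglik(model: GaussianHMM, x: np.ndarray) -> float:
    """Log-likelihood by exhaustive summation over all state paths."""
    T = x.shape[0]
    K = model.n_states
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = model.initial[path[0]]
        for t in range(1, T):
            p *= model.transition[path[t - 1], path[t]]
        for t in range(T):
            p *= scipy.stats.multivariate_normal.pdf(
                x[t], model.means[path[t]], model.covariances[path[t]]
            )
        total += p
    return float(np.log(total))


def _brute_viterbi(model: GaussianHMM, x: np.ndarray) -> np.ndarray:
    T = x.shape[0]
    K = model.n_states
    best, best_lp = None, -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(model.initial[path[0]])
        for t in range(1, T):
            lp += np.log(model.transition[path[t - 1], path[t]])
        for t in range(T):
            lp += scipy.stats.multivariate_normal.logpdf(
                x[t], model.means[path[t]], model.covariances[path[t]]
            )
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best)


def _random_model(K: int, R: int, rng) -> GaussianHMM:
    means = rng.standard_normal((K, R)) * 2
    covs = np.empty((K, R, R))
    for k in range(K):
        w = rng.standard_normal((R, R + 2))
        covs[k] = w @ w.T / (R + 2) + 0.3 * np.eye(R)
    p = rng.uniform(0.2, 1.0, size=(K, K))
    p /= p.sum(axis=1, keepdims=True)
    pi = rng.uniform(0.2, 1.0, size=K)
    pi /= pi.sum()
    return GaussianHMM(means, covs, p, pi)


class TestStandardizeConcatenate:
    def test_zscore_contract(self, rng):
        x = rng.standard_normal((500, 4)) * 3 + 5
        stacked, bounds = standardize_concatenate([x])
        assert np.max(np.abs(stacked.mean(axis=0))) < 1e-10
        assert np.max(np.abs(stacked.std(axis=0) - 1)) < 1e-10
        assert bounds == [0, 500]

    def test_boundaries_bookkeeping(self, rng):
        a, b = rng.standard_normal((100, 3)), rng.standard_normal((250, 3))
        stacked, bounds = standardize_concatenate([a, b])
        assert bounds == [0, 100, 350]
        assert stacked.shape == (350, 3)

    def test_constant_column_rejected(self, rng):
        x = rng.standard_normal((100, 3))
        x[:, 1] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            standardize_concatenate([x])


class TestForwardBackward:
    def test_loglik_matches_exhaustive_enumeration_small(self, rng):
        model = _random_model(2, 1, rng)
        x = rng.standard_normal((3, 1))
        stc = forward_backward(model, x)
        assert stc.loglik == pytest.approx(_brute_loglik(model, x), abs=1e-10)

    @pytest.mark.parametrize("K,T", [(2, 8), (3, 6), (3, 4)])
    def test_loglik_exhaustive_property(self, K, T):
        rng = np.random.default_rng(K * 100 + T)
        model = _random_model(K, 2, rng)
        x = rng.standard_normal((T, 2))
        stc = forward_backward(model, x)
        brute = _brute_loglik(model, x)
        assert stc.loglik == pytest.approx(brute, abs=1e-9)
        assert np.allclose(stc.posteriors.sum(axis=1), 1.0, atol=1e-8)

    def test_identical_states_give_chain_marginals(self, rng):
        # with identical emissions, posteriors reduce to the chain's marginal
        # distribution; starting from the stationary vector they are constant
        p = np.array([[0.7, 0.3], [0.4, 0.6]])
        evals, evecs = np.linalg.eig(p.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi /= pi.sum()
        means = np.zeros((2, 1))
        covs = np.tile(np.eye(1), (2, 1, 1))
        model = GaussianHMM(means, covs, p, pi)
        stc = forward_backward(model, rng.standard_normal((50, 1)))
        assert np.allclose(stc.posteriors, pi, atol=1e-10)

    def test_deterministic_chain_one_hot(self):
        p = np.array([[0.0, 1.0], [1.0, 0.0]])
        model = GaussianHMM(
            np.zeros((2, 1)), np.tile(np.eye(1), (2, 1, 1)), p, np.array([1.0, 0.0])
        )
        stc = forward_backward(model, np.zeros((6, 1)))
        expect = np.tile([[1.0, 0.0], [0.0, 1.0]], (3, 1))
        assert np.allclose(stc.posteriors, expect, atol=1e-12)


class TestViterbi:
    def test_matches_exhaustive_argmax(self, rng):
        model = _random_model(2, 1, rng)
        x = rng.standard_normal((4, 1)) + 1.0
        assert np.array_equal(viterbi(model, x), _brute_viterbi(model, x))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_argmax_k3(self, seed):
        rng = np.random.default_rng(seed)
        model = _random_model(3, 2, rng)
        x = rng.standard_normal((5, 2))
        assert np.array_equal(viterbi(model, x), _brute_viterbi(model, x))

    def test_emission_free_limit_follows_chain(self):
        p = np.array([[0.95, 0.05], [0.3, 0.7]])
        model = GaussianHMM(
            np.zeros((2, 1)), np.tile(np.eye(1), (2, 1, 1)), p, np.array([0.9, 0.1])
        )
        path = viterbi(model, np.zeros((20, 1)))
        assert np.all(path == 0)  # staying in the stickiest state dominates

    def test_single_state_constant(self, rng):
        model = GaussianHMM(
            np.zeros((1, 2)), np.eye(2)[None], np.ones((1, 1)), np.ones(1)
        )
        assert np.all(viterbi(model, rng.standard_normal((10, 2))) == 0)


class TestFitHmm:
    def test_em_loglik_monotone(self, small_model):
        env, _ = simulate_subject(small_model.transition, small_model, 2000, seed=3)
        stacked, bounds = standardize_concatenate([env])
        rng = np.random.default_rng(0)
        init = _kmeans_init(stacked, 3, rng)
        _, _, history = _em_once(stacked, bounds, init, tol=1e-7, max_iter=60)
        diffs = np.diff(history)
        assert np.all(diffs >= -1e-8 * np.maximum(np.abs(history[:-1]), 1.0))

    def test_determinism(self, small_model):
        env, _ = simulate_subject(small_model.transition, small_model, 1500, seed=4)
        stacked, bounds = standardize_concatenate([env])
        m1, _ = fit_hmm(stacked, bounds, 3, n_restarts=2, seed=9, max_iter=40)
        m2, _ = fit_hmm(stacked, bounds, 3, n_restarts=2, seed=9, max_iter=40)
        assert np.array_equal(m1.transition, m2.transition)
        assert np.array_equal(m1.means, m2.means)

    def test_single_state(self, rng):
        x = rng.standard_normal((300, 4))
        model, stcs = fit_hmm(x, [0, 300], K=1)
        assert np.allclose(stcs[0].posteriors, 1.0)
        assert np.array_equal(model.transition, [[1.0]])

    def test_planted_transition_recovery(self):
        # planted K=3, distinct covariances: fitted transitions within 0.05
        truth = default_base_model(K=3, R=6, seed=21, stickiness=0.85)
        env, _ = simulate_subject(truth.transition, truth, 60_000, seed=5)
        stacked, bounds = standardize_concatenate([env])
        model, stcs = fit_hmm(stacked, bounds, 3, n_restarts=2, seed=1, max_iter=120)
        # match labels by mean similarity against the (standardized) truth
        t_means = (truth.means - env.data.mean(axis=0) + 8.0) / env.data.std(axis=0)
        from scipy.optimize import linear_sum_assignment

        cost = np.linalg.norm(model.means[:, None, :] - t_means[None, :, :], axis=2)
        row, col = linear_sum_assignment(cost)
        perm = np.empty(3, dtype=int)
        perm[col] = row
        fitted = model.transition[np.ix_(perm, perm)]
        assert np.max(np.abs(fitted - truth.transition)) < 0.05


class TestOrderStates:
    def test_permutation_is_undone(self, small_model, rng):
        env, _ = simulate_subject(small_model.transition, small_model, 3000, seed=6)
        stacked, bounds = standardize_concatenate([env])
        model, stcs = fit_hmm(stacked, bounds, 3, n_restarts=1, seed=2, max_iter=40)
        perm = np.array([2, 0, 1])
        shuffled = model.permuted(perm)
        shuffled_stcs = [s.permuted(perm) for s in stcs]
        back, back_stcs, _ = order_states(shuffled, shuffled_stcs)
        assert np.allclose(back.transition, model.transition)
        assert np.array_equal(back_stcs[0].path, stcs[0].path)

    def test_fo_sorted_descending(self, small_model):
        env, _ = simulate_subject(small_model.transition, small_model, 3000, seed=8)
        stacked, bounds = standardize_concatenate([env])
        _, stcs = fit_hmm(stacked, bounds, 3, n_restarts=1, seed=3, max_iter=40)
        fo = np.vstack([s.posteriors for s in stcs]).mean(axis=0)
        assert np.all(np.diff(fo) <= 1e-12)


class TestDwellTimes:
    def test_two_runs_of_two_samples(self):
        out = dwell_times(np.array([0, 0, 1, 1]), fs=40.0, K=2)
        assert np.allclose(out, [50.0, 50.0])

    def test_constant_path(self):
        out = dwell_times(np.zeros(120, dtype=int), fs=40.0, K=2)
        assert out[0] == pytest.approx(3000.0)
        assert np.isnan(out[1])

    def test_geometric_dwell_closed_form(self):
        # P_kk = 0.9 gives geometric dwells with mean 10 samples = 250 ms at 40 Hz
        p = np.array([[0.9, 0.1], [0.1, 0.9]])
        model = GaussianHMM(
            np.array([[0.0], [4.0]]),
            np.tile(np.eye(1), (2, 1, 1)),
            p,
            np.array([0.5, 0.5]),
        )
        _, path = simulate_subject(p, model, 120_000, seed=17)
        out = dwell_times(path, fs=40.0, K=2)
        assert np.allclose(out, 250.0, rtol=0.10)
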