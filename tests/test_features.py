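"""Dynamic-connectome features: FO/TP oracles, weighted FC, modularity, blocks."""

import numpy as np
import pytest

from twinstates import (
    GaussianHMM,
    IcnPartition,
    cluster_fc,
    fractional_occupancy,
    icn_pair_fc,
    modularity_fixed_partition,
    state_fc_from_model,
    subject_state_fc,
    transition_probability,
)


class TestFractionalOccupancy:
    def test_constant_path(self):
        assert np.allclose(fractional_occupancy(np.zeros(10, dtype=int), 2), [1, 0])

    def test_strict_alternation(self):
        path = np.tile([0, 1], 50)
        assert np.allclose(fractional_occupancy(path, 2), [0.5, 0.5])

    def test_counting_oracle(self, rng):
        path = rng.integers(0, 4, size=1000)
        fo = fractional_occupancy(path, 4)
        oracle = np.array([(path == k).sum() for k in range(4)]) / 1000
        assert np.array_equal(fo, oracle)

    def test_soft_mode_column_means(self, rng):
        gamma = rng.dirichlet(np.ones(3), size=200)
        assert np.allclose(fractional_occupancy(gamma, 3), gamma.mean(axis=0))


class TestTransitionProbability:
    def test_unvisited_state_uniform_fallback(self):
        tp = transition_probability(np.array([0, 0, 0]), 2)
        assert np.allclose(tp[0], [1, 0])
        assert np.allclose(tp[1], [0.5, 0.5])

    def test_alternating_path(self):
        tp = transition_probability(np.array([0, 1, 0, 1, 0]), 2)
        assert np.allclose(tp, [[0, 1], [1, 0]])

    def test_long_chain_recovers_generator(self):
        from twinstates import default_base_model, simulate_subject

        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 1.0, (3, 3))
        p /= p.sum(axis=1, keepdims=True)
        model = default_base_model(K=3, R=2, seed=0)
        _, path = simulate_subject(p, model, 100_000, seed=9)
        tp = transition_probability(path, 3)
        assert np.max(np.abs(tp - p)) < 0.01

    def test_fo_matches_tp_stationary_distribution(self):
        from twinstates import default_base_model, simulate_subject

        model = default_base_model(K=3, R=2, seed=1, stickiness=0.8)
        _, path = simulate_subject(model.transition, model, 100_000, seed=10)
        tp = transition_probability(path, 3)
        evals, evecs = np.linalg.eig(tp.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi /= pi.sum()
        assert np.max(np.abs(fractional_occupancy(path, 3) - pi)) < 0.02


class TestSubjectStateFc:
    def test_all_one_weights_equal_plain_pearson(self, rng):
        x = rng.standard_normal((400, 5))
        fcs, valid = subject_state_fc(x, np.ones((400, 1)))
        assert valid[0]
        assert np.allclose(fcs[0], np.corrcoef(x.T), atol=1e-12)

    def test_planted_regimes_recovered(self, rng):
        # two interleaved regimes with opposite correlation, exact labels
        n = 4000
        z = rng.standard_normal(n)
        e = rng.standard_normal(n) * 0.4
        labels = np.tile([0, 1], n // 2)
        y = np.where(labels == 0, z + e, -z + e)
        x = np.column_stack([z, y])
        gamma = np.column_stack([labels == 0, labels == 1]).astype(float)
        fcs, _ = subject_state_fc(x, gamma)
        r = np.corrcoef(z[labels == 0], (z + e)[labels == 0])[0, 1]
        assert fcs[0][0, 1] == pytest.approx(r, abs=0.05)
        assert fcs[1][0, 1] == pytest.approx(-r, abs=0.05)

    def test_perfectly_correlated_columns(self, rng):
        z = rng.standard_normal(100)
        x = np.column_stack([z, 2 * z + 1])
        fcs, _ = subject_state_fc(x, np.ones((100, 1)))
        assert fcs[0][0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_low_weight_state_flagged_missing(self, rng):
        x = rng.standard_normal((100, 3))
        gamma = np.column_stack([np.ones(100) * 0.99, np.ones(100) * 0.01])
        fcs, valid = subject_state_fc(x, gamma)
        assert valid[0] and not valid[1]
        assert np.all(np.isnan(fcs[1]))


class TestStateFcFromModel:
    def test_diagonal_covariance_gives_identity(self):
        covs = np.array([np.diag([1.0, 2.0, 3.0])])
        assert np.allclose(state_fc_from_model(covs), np.eye(3))

    def test_known_off_diagonal(self):
        covs = np.array([[[1.0, 0.5], [0.5, 1.0]]])
        assert state_fc_from_model(covs)[0][0, 1] == pytest.approx(0.5)

    def test_random_spd_elementwise_oracle(self, rng):
        w = rng.standard_normal((4, 6))
        cov = w @ w.T + 0.5 * np.eye(4)
        fc = state_fc_from_model(cov[None])[0]
        for i in range(4):
            for j in range(4):
                assert fc[i, j] == pytest.approx(
                    cov[i, j] / np.sqrt(cov[i, i] * cov[j, j])
                )


class TestModularity:
    def test_two_disconnected_cliques(self):
        # two equal modules with no between edges: Q = 1 - 1/c = 0.5
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        part = IcnPartition(("m1", "m2"), (0, 0, 1, 1))
        assert modularity_fixed_partition(a, part) == pytest.approx(0.5)

    def test_single_module_zero(self, rng):
        w = np.abs(rng.standard_normal((5, 5)))
        a = 0.5 * (w + w.T)
        part = IcnPartition(("all",), (0,) * 5)
        assert modularity_fixed_partition(a, part) == pytest.approx(0.0, abs=1e-12)

    def test_double_sum_formula_oracle(self, rng):
        w = np.abs(rng.standard_normal((8, 8)))
        a = 0.5 * (w + w.T)
        np.fill_diagonal(a, 0.0)
        ci = rng.integers(0, 2, size=8)
        part = IcnPartition(("a", "b"), tuple(int(c) for c in ci))
        q = modularity_fixed_partition(a, part)
        two_m = a.sum()
        k = a.sum(axis=1)
        oracle = sum(
            (a[i, j] - k[i] * k[j] / two_m) / two_m
            for i in range(8)
            for j in range(8)
            if ci[i] == ci[j]
        )
        assert q == pytest.approx(oracle, abs=1e-12)

    def test_matches_networkx_reference(self, rng):
        import networkx as nx

        w = np.abs(rng.standard_normal((10, 10)))
        a = 0.5 * (w + w.T)
        np.fill_diagonal(a, 0.0)
        ci = rng.integers(0, 3, size=10)
        part = IcnPartition(("a", "b", "c"), tuple(int(c) for c in ci))
        g = nx.from_numpy_array(a)
        communities = [set(np.flatnonzero(ci == c)) for c in range(3)]
        ref = nx.community.modularity(g, communities, weight="weight")
        assert modularity_fixed_partition(a, part) == pytest.approx(ref, abs=1e-10)


class TestClusterFc:
    def test_single_edge_mask(self, rng):
        fcs = rng.standard_normal((3, 4, 4))
        fcs = (fcs + fcs.transpose(0, 2, 1)) / 2
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 2] = True
        out = cluster_fc(fcs, mask)
        assert np.allclose(out, fcs[:, 0, 2])

    def test_identity_fc_all_edges_zero(self):
        fcs = np.tile(np.eye(4), (2, 1, 1))
        mask = np.ones((4, 4), dtype=bool)
        assert np.allclose(cluster_fc(fcs, mask), 0.0)

    def test_masked_mean_oracle(self, rng):
        fcs = rng.standard_normal((2, 5, 5))
        fcs = (fcs + fcs.transpose(0, 2, 1)) / 2
        mask = rng.random((5, 5)) > 0.5
        mask = mask | mask.T
        np.fill_diagonal(mask, False)
        if not mask.any():
            mask[0, 1] = mask[1, 0] = True
        out = cluster_fc(fcs, mask)
        for k in range(2):
            vals = [fcs[k, i, j] for i in range(5) for j in range(5) if mask[i, j]]
            assert out[k] == pytest.approx(np.mean(vals))


class TestIcnPairFc:
    def test_hand_computed_two_network_case(self):
        fc = np.array(
            [
                [1.0, 0.2, 0.3, 0.4],
                [0.2, 1.0, 0.5, 0.6],
                [0.3, 0.5, 1.0, 0.7],
                [0.4, 0.6, 0.7, 1.0],
            ]
        )
        part = IcnPartition(("n1", "n2"), (0, 0, 1, 1))
        out = icn_pair_fc(fc[None], part)
        assert out[("n1", "n1")][0] == pytest.approx(0.2)
        assert out[("n2", "n2")][0] == pytest.approx(0.7)
        assert out[("n1", "n2")][0] == pytest.approx((0.3 + 0.4 + 0.5 + 0.6) / 4)

    def test_region_permutation_invariance(self, rng):
        fcs = rng.standard_normal((2, 8, 8))
        fcs = (fcs + fcs.transpose(0, 2, 1)) / 2
        ci = (0, 0, 1, 1, 2, 2, 1, 0)
        part = IcnPartition(("a", "b", "c"), ci)
        perm = rng.permutation(8)
        fcs_p = fcs[:, perm][:, :, perm]
        part_p = IcnPartition(("a", "b", "c"), tuple(ci[i] for i in perm))
        out = icn_pair_fc(fcs, part)
        out_p = icn_pair_fc(fcs_p, part_p)
        for key in out:
            assert np.allclose(out[key], out_p[key])

    def test_seven_networks_yield_28_entries(self, rng):
        part = IcnPartition.balanced(21, 7)
        fcs = rng.standard_normal((1, 21, 21))
        fcs = (fcs + fcs.transpose(0, 2, 1)) / 2
        out = icn_pair_fc(fcs, part)
        assert len(out) == 28  # 21 between + 7 within
        within = [k for k in out if k[0] == k[1]]
        assert len(within) == 7
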