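"""Similarity ANCOVA screen: distances, calibration, Bayes factors, power."""

import numpy as np
import pytest
import scipy.stats

from twinstates import (
    TwinPairRecord,
    ancova_power,
    bf01_bic,
    componentwise_twoway_ancova,
    eta2_to_f,
    min_detectable_f,
    pair_distance,
    sibling_ancova,
    subject_origin_distance,
)
from twinstates.surrogates import NullOrigin


def _make_pairs(n_mz, n_dz, n_ur, rng):
    pairs = []
    zygs = ["MZ"] * n_mz + ["DZ"] * n_dz + ["UR"] * n_ur
    for i, z in enumerate(zygs):
        pairs.append(
            TwinPairRecord(
                pair_id=f"P{i:04d}",
                subject_a=f"P{i:04d}a",
                subject_b=f"P{i:04d}b",
                zygosity=z,
                pair_sex="F" if rng.random() < 0.5 else "M",
                age_diff=float(rng.uniform(0, 1)),
            )
        )
    return pairs


class TestDistances:
    def test_identical_vectors_zero(self):
        x = np.arange(5.0)
        assert pair_distance(x, x) == 0.0

    def test_unit_difference(self):
        a = np.zeros(4)
        b = np.zeros(4)
        b[2] = 1.0
        assert pair_distance(a, b) == 1.0

    def test_arithmetic_oracle(self, rng):
        a, b = rng.standard_normal(36), rng.standard_normal(36)
        assert pair_distance(a, b) == pytest.approx(
            np.sqrt(np.sum((a - b) ** 2)), rel=1e-12
        )

    def test_origin_distance_zero_at_origin(self, rng):
        o = NullOrigin("fo", "alpha", rng.standard_normal(6), 5)
        assert subject_origin_distance(o.origin, o) == 0.0

    def test_origin_shift_lipschitz(self, rng):
        x = rng.standard_normal(6)
        o = rng.standard_normal(6)
        delta = 0.3
        o2 = o.copy()
        o2[0] += delta
        d1 = subject_origin_distance(x, o)
        d2 = subject_origin_distance(x, o2)
        assert abs(d1 - d2) <= delta + 1e-12

    def test_origin_distance_norm_oracle(self, rng):
        x, o = rng.standard_normal(9), rng.standard_normal(9)
        assert subject_origin_distance(x, o) == pytest.approx(
            np.linalg.norm(x - o), rel=1e-12
        )


class TestSiblingAncova:
    def test_denominator_df_for_463_pairs(self, rng):
        pairs = _make_pairs(206, 112, 145, rng)
        d = rng.standard_normal(463)
        res = sibling_ancova(d, pairs)
        assert res.df == (2, 458)
        assert res.p_bonf == min(1.0, 20 * res.p)

    def test_null_p_values_uniform(self, rng):
        pairs = _make_pairs(40, 30, 30, rng)
        pvals = []
        for _ in range(500):
            d = rng.standard_normal(100)
            pvals.append(sibling_ancova(d, pairs).p)
        stat = scipy.stats.kstest(pvals, "uniform")
        assert stat.pvalue > 0.01

    def test_power_with_planted_ordering(self, rng):
        # group means ordered MZ < DZ < UR at Cohen's f = 0.25, n = 300 pairs
        pairs = _make_pairs(100, 100, 100, rng)
        delta = 0.25 / np.sqrt(2.0 / 3.0)
        means = {"MZ": -delta, "DZ": 0.0, "UR": delta}
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            d = np.array([means[p.zygosity] for p in pairs]) + rng.standard_normal(300)
            if sibling_ancova(d, pairs).p < 0.05:
                hits += 1
        assert hits / n_rep > 0.95

    def test_group_means_reported(self, rng):
        pairs = _make_pairs(5, 5, 5, rng)
        d = np.concatenate([np.full(5, 1.0), np.full(5, 2.0), np.full(5, 3.0)])
        res = sibling_ancova(d, pairs)
        assert res.group_means["MZ"] == pytest.approx(1.0)
        assert res.group_means["UR"] == pytest.approx(3.0)


class TestTwoWayAncova:
    def test_component_independent_effect_no_interaction(self, rng):
        pairs = _make_pairs(20, 15, 15, rng)
        shift = {"MZ": -0.5, "DZ": 0.0, "UR": 0.5}
        f_int = []
        for _ in range(200):
            base = np.array([shift[p.zygosity] for p in pairs])[:, None]
            d = base + rng.standard_normal((50, 4))
            out = componentwise_twoway_ancova(d, pairs)
            f_int.append(out["interaction"]["F"])
        assert np.mean(f_int) == pytest.approx(1.0, abs=0.25)

    def test_global_null_f_distributed(self, rng):
        pairs = _make_pairs(15, 15, 15, rng)
        d = rng.standard_normal((45, 3))
        out = componentwise_twoway_ancova(d, pairs)
        for key in ("sibling_status", "component", "interaction"):
            assert out[key]["p"] > 1e-4

    def test_hand_sized_normal_equations_oracle(self, rng):
        pairs = _make_pairs(4, 4, 0, rng)
        d = rng.standard_normal((8, 2))
        out = componentwise_twoway_ancova(d, pairs, ["x", "y"])
        # brute force: build the pooled design explicitly
        y = d.ravel()
        zyg = np.repeat([p.zygosity for p in pairs], 2)
        comp = np.tile([0, 1], 8)
        age = np.repeat([p.age_diff for p in pairs], 2)
        sex = np.repeat([1.0 if p.pair_sex == "F" else 0.0 for p in pairs], 2)
        z_dz = (zyg == "DZ").astype(float)
        c1 = (comp == 1).astype(float)
        ones = np.ones(16)

        def rss(*cols):
            x = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            return np.sum((y - x @ beta) ** 2)

        rss_add = rss(ones, z_dz, c1, age, sex)
        rss_full = rss(ones, z_dz, c1, z_dz * c1, age, sex)
        df2 = 16 - 6
        f_oracle = ((rss_add - rss_full) / 1) / (rss_full / df2)
        assert out["interaction"]["F"] == pytest.approx(f_oracle, rel=1e-8)


class TestBayesFactor:
    def test_strong_effect_favours_h1(self, rng):
        pairs = _make_pairs(100, 100, 100, rng)
        means = {"MZ": -2.0, "DZ": 0.0, "UR": 2.0}
        d = np.array([means[p.zygosity] for p in pairs]) + rng.standard_normal(300)
        assert bf01_bic(d, pairs) < 0.01  # BF10 > 100

    def test_null_data_prefers_h0(self, rng):
        pairs = _make_pairs(140, 130, 130, rng)
        n_h0 = 0
        for _ in range(200):
            d = rng.standard_normal(400)
            if bf01_bic(d, pairs) > 1.0:
                n_h0 += 1
        assert n_h0 / 200 >= 0.80

    def test_reciprocal_identity(self, rng):
        pairs = _make_pairs(20, 20, 20, rng)
        d = rng.standard_normal(60)
        bf01 = bf01_bic(d, pairs)
        assert bf01 * (1.0 / bf01) == pytest.approx(1.0)
        res = sibling_ancova(d, pairs)
        assert res.bf01 == pytest.approx(bf01)


class TestPowerAnalysis:
    def test_minimum_detectable_effect_size(self):
        f = min_detectable_f(463, k_groups=3, n_covariates=2, alpha=0.05, power=0.80)
        assert f == pytest.approx(0.145, abs=0.003)

    def test_eta2_to_f_closed_form(self):
        assert eta2_to_f(0.021) == pytest.approx(np.sqrt(0.021 / 0.979), rel=1e-12)
        assert eta2_to_f(0.021) == pytest.approx(0.1465, abs=0.0005)

    def test_power_at_reported_effect(self):
        assert ancova_power(0.145, 463, 3, 2, 0.05) >= 0.80

    def test_detectable_f_decreases_with_n(self):
        grid = [100, 200, 400, 800, 1600]
        fs = [min_detectable_f(n) for n in grid]
        assert all(a > b for a, b in zip(fs, fs[1:]))
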