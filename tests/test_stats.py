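from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clampkinetics.stats import bh_fdr, compare_groups, correlate, pearson_correlation, rank_sum_test


def exact_rank_sum_p(x, y):
    """Permutation-enumeration two-sided p for the rank-sum statistic."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n, m = x.size, y.size
    observed = ranks[:n].sum()
    sums = np.array([sum(c) for c in combinations(ranks, n)])
    mu = sums.mean()
    p = np.mean(np.abs(sums - mu) >= abs(observed - mu) - 1e-12)
    return float(p)


def brute_force_bh(p):
    """min over j >= i of p_(j) * m / j, capped at 1, back in input order."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(1.0, min(sorted_p[j] * m / (j + 1) for j in range(i, m)))
    out = np.empty(m)
    out[order] = adj
    return out


class TestRankSum:
    def test_enumerated_small_sample(self):
        _, p = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1.0 / 3.0)

    def test_identical_samples_not_significant(self):
        x = np.arange(20.0)
        _, p = rank_sum_test(x, x)
        assert p > 0.95

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(1.0, 1.0, size=9)
        assert rank_sum_test(x, y)[1] == pytest.approx(rank_sum_test(y, x)[1])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=5),
        st.lists(st.floats(-50, 50), min_size=2, max_size=5),
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_exact_p_matches_enumeration(self, x, y):
        pooled = x + y
        if len(set(pooled)) != len(pooled):  # exact path applies to tie-free data
            return
        _, p = rank_sum_test(x, y)
        assert p == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)


class TestBhFdr:
    def test_worked_example(self):
        assert np.allclose(bh_fdr([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_fdr([0.07] * 5), 0.07)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_brute_force(self, ps):
        assert np.allclose(bh_fdr(ps), brute_force_bh(ps), atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=15))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_adjusted_at_least_raw(self, ps):
        adj = bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_negative(self):
        x = np.arange(5.0)
        r, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r, _ = pearson_correlation([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
        assert r == pytest.approx(0.5)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        r, _ = pearson_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_spearman_flag(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, np.exp(x), method="spearman")
        assert r == pytest.approx(1.0)


class TestCompareGroups:
    @staticmethod
    def _table(rng, shift=0.0, n=20):
        rows = []
        for g, mu in [("NGT", 0.2), ("T2DM", 0.2 * np.exp(-shift))]:
            for _ in range(n):
                rows.append({"group": g, "k_Iout": mu * np.exp(0.2 * rng.standard_normal())})
        return pd.DataFrame(rows)

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(3)
        df = self._table(rng, shift=0.7)
        out = compare_groups(df, ["k_Iout"])
        assert bool(out.significant.iloc[0])
        assert out.p_fdr.iloc[0] < 0.05

    def test_null_calibration_under_permutation(self):
        """With no group structure the BH-corrected false-positive rate stays
        near (below) the nominal level."""
        false_pos = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng([7, seed])
            df = self._table(rng, shift=0.0, n=12)
            out = compare_groups(df, ["k_Iout"])
            false_pos += int(out.significant.any())
        assert false_pos <= 0.12 * n_rep

    def test_single_test_bh_is_identity(self):
        rng = np.random.default_rng(5)
        df = self._table(rng, shift=0.3)
        out = compare_groups(df, ["k_Iout"])
        assert out.p_fdr.iloc[0] == pytest.approx(out.p_raw.iloc[0])

    def test_quartiles_reported(self):
        rng = np.random.default_rng(6)
        df = self._table(rng)
        out = compare_groups(df, ["k_Iout"])
        row = out.iloc[0]
        assert row.q1_a <= row.median_a <= row.q3_a

    def test_undersized_group_excluded(self):
        rng = np.random.default_rng(8)
        df = self._table(rng)
        df = pd.concat([df, pd.DataFrame([{"group": "borderline", "k_Iout": 0.1}])])
        out = compare_groups(df, ["k_Iout"])
        assert set(out.group_a) | set(out.group_b) == {"NGT", "T2DM"}

    def test_correlate_frame(self):
        rng = np.random.default_rng(9)
        k = rng.lognormal(-1.6, 0.3, size=40)
        df = pd.DataFrame({"k_Iout": k, "isi": 50 * k * np.exp(0.1 * rng.standard_normal(40))})
        out = correlate(df, [("k_Iout", "isi")])
        assert out.r.iloc[0] > 0.8
        assert out.p.iloc[0] < 1e-6
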