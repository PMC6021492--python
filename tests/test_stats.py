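"""Spearman and Mann-Whitney against brute-force oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ifnsig import compare_groups, mann_whitney, spearman_matrix
from ifnsig.stats import exact_mann_whitney_p


def _average_ranks(values):
    """Plain average-rank computation by enumeration (oracle)."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    return np.array(ranks)


def _spearman_bruteforce(a, b):
    """Pearson correlation of hand-computed average ranks (oracle)."""
    ra, rb = _average_ranks(a), _average_ranks(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    return float((ra * rb).sum() / denom)


class TestSpearman:
    def test_perfect_monotone(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [10, 20, 30, 40, 50]})
        corr = spearman_matrix(df)
        assert corr.rho.loc["x", "y"] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        # integer draws force ties
        a = rng.integers(0, 4, size=n).astype(float)
        b = rng.integers(0, 4, size=n).astype(float)
        if np.all(a == a[0]) or np.all(b == b[0]):
            return
        corr = spearman_matrix(pd.DataFrame({"a": a, "b": b}))
        assert corr.rho.loc["a", "b"] == pytest.approx(
            _spearman_bruteforce(a, b), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        c1 = spearman_matrix(pd.DataFrame({"a": a, "b": b}))
        c2 = spearman_matrix(pd.DataFrame({"a": np.exp(a), "b": b**3}))
        assert c1.rho.loc["a", "b"] == pytest.approx(
            c2.rho.loc["a", "b"], abs=1e-12)

    def test_constant_column_reported_undefined(self):
        df = pd.DataFrame({"a": [1.0] * 6, "b": [1, 2, 3, 4, 5, 6]})
        corr = spearman_matrix(df)
        assert np.isnan(corr.rho.loc["a", "b"])
        assert any("constant" in reason
                   for *_, reason in corr.undefined_pairs)

    def test_pairwise_complete(self):
        df = pd.DataFrame({
            "a": [1, 2, 3, 4, 5, np.nan],
            "b": [2, 4, 6, 8, 10, 12.0],
        })
        corr = spearman_matrix(df)
        assert corr.n.loc["a", "b"] == 5
        assert corr.rho.loc["a", "b"] == pytest.approx(1.0)


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.0)

    def test_full_separation_exact_p(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.1)  # 2/20 assignments

    def test_exact_distribution_normalizes(self):
        # tail counts over the full enumeration cover every assignment
        a, b = [1.0, 3.0, 5.0], [2.0, 4.0]
        u, p = exact_mann_whitney_p(a, b)
        assert 0 < p <= 1

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 2**31 - 1))
    def test_asymptotic_close_to_exact(self, seed):
        rng = np.random.default_rng(seed)
        # the continuity-corrected normal approximation holds the 0.02 band
        # from group size 5 up (at 4 the worst gap reaches ~0.03)
        n_a, n_b = int(rng.integers(5, 9)), int(rng.integers(5, 9))
        a = rng.normal(size=n_a)
        b = rng.normal(size=n_b)  # continuous, no ties
        exact = mann_whitney(a, b, exact_max_n=8)
        approx = mann_whitney(a, b, exact_max_n=0)
        assert approx.method == "asymptotic"
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_power_under_shift(self):
        # two pooled-SD shift at the reference group sizes should be
        # detected in nearly every run
        rng = np.random.default_rng(123)
        hits = 0
        runs = 200
        for _ in range(runs):
            a = rng.normal(0.0, 1.0, size=31)
            b = rng.normal(2.0, 1.0, size=8)
            if mann_whitney(a, b).p_value < 0.05:
                hits += 1
        assert hits / runs >= 0.90

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestCompareGroups:
    def test_all_identical_cohort(self):
        df = pd.DataFrame({
            "genotype": ["BRAF"] * 4 + ["GNAQ/GNA11"] * 4,
            "M_pre": [5.0] * 8,
        })
        res = compare_groups(df, which="pre", markers=["M"])
        assert res[0].p_value == pytest.approx(1.0)

    def test_unlabeled_line_rejected(self):
        df = pd.DataFrame({"genotype": ["BRAF", ""], "M_pre": [1.0, 2.0]})
        with pytest.raises(ValueError, match="genotype"):
            compare_groups(df, which="pre", markers=["M"])

    def test_simulated_uveal_deficit_detected(self):
        # uveal medians at 0.2x the cutaneous scale; significant in >= 90%
        # of seeded runs
        hits, runs = 0, 100
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            cut = 10.0 ** rng.normal(np.log10(30.0), 0.4, size=31)
            uvm = 10.0 ** rng.normal(np.log10(6.0), 0.4, size=8)
            df = pd.DataFrame({
                "genotype": ["BRAF"] * 31 + ["GNAQ/GNA11"] * 8,
                "NGFR_pre": np.concatenate([cut, uvm]),
            })
            res = compare_groups(df, which="pre", markers=["NGFR"])
            if res[0].p_value < 0.05:
                hits += 1
        assert hits / runs >= 0.90

    def test_reference_cohort_group_sizes(self, marker_table):
        res = compare_groups(marker_table, which="pre")
        assert all(c.n_a == 31 and c.n_b == 8 for c in res)
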