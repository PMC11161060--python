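"""Subset-vs-bulk inference: bootstrap median test against the exact
enumeration oracle, hypergeometric overlap against brute-force draw
enumeration, CDF shifts and subset median fold-changes."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from markretain.stats import (
    bh_adjust,
    bootstrap_median_test,
    distribution_shift,
    exact_median_test,
    hypergeometric_enrichment,
    subset_median_foldchange,
)


def brute_force_overlap_tail(universe, set_a, set_b):
    """Oracle: P(random |B|-subset overlaps A by >= observed) by full
    enumeration of all C(N, |B|) draws."""
    universe, set_a = list(universe), set(set_a)
    observed = len(set_a & set(set_b))
    hits = total = 0
    for draw in combinations(universe, len(set_b)):
        total += 1
        if len(set_a & set(draw)) >= observed:
            hits += 1
    return hits / total


class TestBootstrapMedianTest:
    def test_matches_exact_enumeration_on_tiny_population(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0],
                           index=pd.Index(list("abcde"), name="gene_id"))
        exact = exact_median_test(values, ["d", "e"])
        assert exact["p_upper"] == pytest.approx(0.1)  # 1 of C(5,2)=10 draws
        boot = bootstrap_median_test(values, ["d", "e"], n_iter=100_000, seed=5)
        se = np.sqrt(0.1 * 0.9 / 100_000)
        assert abs(boot.p_upper - 0.1) < 3 * se + 2 / 100_001

    def test_single_maximum_gene(self):
        values = pd.Series(np.arange(1.0, 21.0),
                           index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"))
        boot = bootstrap_median_test(values, ["g19"], n_iter=50_000, seed=1)
        # drawing the max among 20 distinct values has probability 1/20
        assert boot.p_upper == pytest.approx(1 / 20, abs=3 * np.sqrt(0.05 * 0.95 / 50_000))
        assert boot.direction == "higher"

    def test_probabilities_positive_and_ties_double_counted(self, rng):
        values = pd.Series(rng.integers(0, 3, 30).astype(float),
                           index=pd.Index([f"g{i}" for i in range(30)], name="gene_id"))
        res = bootstrap_median_test(values, [f"g{i}" for i in range(5)],
                                    n_iter=2000, seed=3)
        assert 0 < res.p_upper <= 1 and 0 < res.p_lower <= 1
        assert res.count_ge + res.count_le >= res.n_iter

    def test_deterministic_given_seed(self):
        values = pd.Series(np.arange(50.0),
                           index=pd.Index([f"g{i}" for i in range(50)], name="gene_id"))
        a = bootstrap_median_test(values, ["g1", "g2", "g3"], n_iter=2000, seed=9)
        b = bootstrap_median_test(values, ["g1", "g2", "g3"], n_iter=2000, seed=9)
        assert (a.count_ge, a.count_le) == (b.count_ge, b.count_le)

    def test_subset_errors(self):
        values = pd.Series([1.0, 2.0], index=pd.Index(["a", "b"], name="gene_id"))
        with pytest.raises(ValueError):
            bootstrap_median_test(values, [], n_iter=2000)
        with pytest.raises(ValueError):
            bootstrap_median_test(values, ["a", "b"], n_iter=2000)
        with pytest.raises(KeyError, match="missing"):
            bootstrap_median_test(values, ["zz"], n_iter=2000)

    def test_low_iteration_count_warns(self):
        values = pd.Series(np.arange(10.0),
                           index=pd.Index([f"g{i}" for i in range(10)], name="gene_id"))
        with pytest.warns(UserWarning, match="unstable"):
            bootstrap_median_test(values, ["g0"], n_iter=100, seed=0)


class TestExactMedianTest:
    def test_minimum_single_draw(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0],
                           index=pd.Index(list("abcd"), name="gene_id"))
        res = exact_median_test(values, ["a"])
        assert res["p_lower"] == pytest.approx(1 / 4)

    def test_tail_overlap_identity(self, rng):
        # p_upper + p_lower = 1 + P(null median == observed)
        vals = rng.integers(0, 4, 9).astype(float)
        values = pd.Series(vals, index=pd.Index([f"g{i}" for i in range(9)], name="gene_id"))
        subset = ["g0", "g1", "g2"]
        res = exact_median_test(values, subset)
        obs = np.median(values[subset])
        eq = sum(
            1 for c in combinations(np.sort(vals), 3) if np.median(c) == obs
        ) / comb(9, 3)
        assert res["p_upper"] + res["p_lower"] == pytest.approx(1 + eq)

    def test_refuses_combinatorial_blowup(self):
        values = pd.Series(np.arange(60.0),
                           index=pd.Index([f"g{i}" for i in range(60)], name="gene_id"))
        with pytest.raises(ValueError, match="combinations"):
            exact_median_test(values, [f"g{i}" for i in range(20)])


class TestHypergeometricEnrichment:
    def test_closed_form_example(self):
        universe = [f"g{i}" for i in range(10)]
        a, b = universe[:5], universe[1:5]
        res = hypergeometric_enrichment(a, b, universe)
        assert res.overlap == 4
        assert res.p_value == pytest.approx(5 / 210)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        res = hypergeometric_enrichment(universe[:3], universe[3:6], universe)
        assert res.p_value == pytest.approx(1.0)
        assert res.expected_overlap == pytest.approx(9 / 8)

    @pytest.mark.parametrize("n,ka,kb,seed", [(8, 3, 4, 0), (10, 5, 4, 1), (12, 6, 5, 2), (12, 4, 4, 3)])
    def test_matches_brute_force_enumeration(self, n, ka, kb, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(n)]
        a = list(rng.choice(universe, ka, replace=False))
        b = list(rng.choice(universe, kb, replace=False))
        res = hypergeometric_enrichment(a, b, universe)
        assert res.p_value == pytest.approx(brute_force_overlap_tail(universe, a, b))

    def test_symmetric_in_a_and_b(self, rng):
        universe = [f"g{i}" for i in range(12)]
        a = list(rng.choice(universe, 5, replace=False))
        b = list(rng.choice(universe, 7, replace=False))
        p_ab = hypergeometric_enrichment(a, b, universe).p_value
        p_ba = hypergeometric_enrichment(b, a, universe).p_value
        assert p_ab == pytest.approx(p_ba)

    def test_nested_set_maximal_overlap(self):
        universe = [f"g{i}" for i in range(12)]
        a, b = universe[:6], universe[:3]  # B subset of A
        res = hypergeometric_enrichment(a, b, universe)
        assert res.p_value == pytest.approx(brute_force_overlap_tail(universe, a, b))

    def test_non_subset_input_names_offenders(self):
        with pytest.raises(ValueError, match="zz"):
            hypergeometric_enrichment(["a", "zz"], ["a"], ["a", "b"])


class TestDistributionShift:
    def test_subset_equals_bulk(self, rng):
        vals = rng.standard_normal(50)
        res = distribution_shift(vals, vals, n_iter=0)
        assert res.ks_distance == 0.0 and res.median_diff == 0.0

    def test_location_shift_recovered(self, rng):
        bulk = rng.standard_normal(201)
        res = distribution_shift(bulk + 2.5, bulk, n_iter=0)
        assert res.median_diff == pytest.approx(2.5)

    def test_boosted_subset_detected(self, small_dataset):
        from markretain.genes import aggregate_gene_signal, build_gene_table

        d = small_dataset
        lv = {k: aggregate_gene_signal(t, d.annotation) for k, t in d.tracks.items()}
        table = build_gene_table(lv["k4_ctrl"], lv["k4_treated"], lv["k27_ctrl"], lv["k27_treated"])
        ret = table.loc[table["detectable"], "retention"]
        res = distribution_shift(ret.loc[d.subset].to_numpy(), ret.to_numpy(),
                                 n_iter=20_000, seed=2)
        assert res.bootstrap.direction == "higher"
        assert res.bootstrap.p_upper < 0.05

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            distribution_shift([], [1.0, 2.0])


class TestSubsetMedianFoldchange:
    def idx(self, n):
        return pd.Index([f"p{i}" for i in range(n)], name="gene_id")

    def test_simple_median(self):
        fc = pd.Series([1.2, 1.5, 0.9], index=self.idx(3))
        with pytest.warns(UserWarning):  # size-3 boundary is fine; empty set warns below
            out = subset_median_foldchange(fc, {"all": list(fc.index), "none": []}, seed=0)
        assert out.loc["all", "median_fc"] == pytest.approx(1.2)
        assert "none" not in out.index

    def test_constant_values_have_zero_se(self):
        fc = pd.Series([2.0] * 8, index=self.idx(8))
        out = subset_median_foldchange(fc, {"s": list(fc.index[:5])}, seed=1)
        assert out.loc["s", "median_fc"] == 2.0 and out.loc["s", "se"] == 0.0

    def test_nested_subsets_order_statistics(self):
        fc = pd.Series(np.arange(1.0, 11.0), index=self.idx(10))
        big = list(fc.index)
        small = list(fc.index[5:])  # the top half of the big set
        out = subset_median_foldchange(fc, {"big": big, "small": small}, seed=2)
        assert out.loc["small", "median_fc"] >= out.loc["big", "median_fc"]

    def test_tiny_subset_flagged_unreliable(self):
        fc = pd.Series([1.0, 2.0, 3.0, 4.0], index=self.idx(4))
        with pytest.warns(UserWarning, match="SE unreliable"):
            out = subset_median_foldchange(fc, {"s": ["p0", "p1"]}, seed=3)
        assert bool(out.loc["s", "se_unreliable"])


def test_bh_adjustment_is_monotone_and_bounded(rng):
    p = rng.uniform(0, 1, 20)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
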