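"""Directional gene-set classification and intersection z-scores."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from stresscycle.transcriptome_sets import (
    FoldChangeTable,
    analytic_intersection_zscore,
    classify_directional_sets,
    compare_conditions,
    compute_fold_changes,
    mc_intersection_zscore,
)


def hypergeometric_moments_by_enumeration(N: int, n1: int, n2: int):
    """Exact null moments of |A ∩ B| by summing the hypergeometric pmf.

    Independent oracle: exact rational arithmetic over the full support,
    no shared code with the closed form under test.
    """
    total = math.comb(N, n2)
    mean = Fraction(0)
    second = Fraction(0)
    for k in range(0, min(n1, n2) + 1):
        p = Fraction(math.comb(n1, k) * math.comb(N - n1, n2 - k), total)
        mean += k * p
        second += k * k * p
    return mean, second - mean**2


class TestComputeFoldChanges:
    @pytest.mark.parametrize(
        "stress, control, pseudocount, expected",
        [
            ({"gA": 40, "gB": 5}, {"gA": 10, "gB": 10}, 0.0, {"gA": 4.0, "gB": 0.5}),
            ({"gA": 7, "gB": 2}, {"gA": 7, "gB": 2}, 0.0, {"gA": 1.0, "gB": 1.0}),
            ({"gA": 0}, {"gA": 8}, 1.0, {"gA": 1 / 9}),
        ],
    )
    def test_ratio_examples(self, stress, control, pseudocount, expected):
        table = compute_fold_changes(stress, control, pseudocount)
        assert table.entries == pytest.approx(expected)
        assert table.n_excluded == 0

    def test_genes_absent_from_one_table_are_dropped_and_counted(self):
        table = compute_fold_changes({"gA": 4, "gB": 1}, {"gA": 2, "gC": 3})
        assert set(table.entries) == {"gA"}
        assert table.n_excluded == 2

    def test_zero_control_without_pseudocount_excludes_gene(self):
        table = compute_fold_changes({"gA": 5, "gB": 4}, {"gA": 0, "gB": 2})
        assert set(table.entries) == {"gB"}
        assert table.n_excluded == 1

    def test_disjoint_tables_error(self):
        with pytest.raises(ValueError, match="no common genes"):
            compute_fold_changes({"gA": 1}, {"gB": 1})

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            compute_fold_changes({"gA": 1}, {"gA": 1}, pseudocount=-1)


class TestClassifyDirectionalSets:
    def test_strict_cutoffs_exclude_boundary_genes(self):
        fc = FoldChangeTable(
            "x", {"g1": 3.0, "g2": 2.0, "g3": 0.4, "g4": 1.0, "g5": 0.5, "g6": 2.5}
        )
        sets = classify_directional_sets(fc)
        assert sets.up == {"g1", "g6"}
        assert sets.down == {"g3"}
        assert sets.unclassified == {"g2", "g4", "g5"}

    def test_unregulated_table_yields_empty_sets(self):
        fc = FoldChangeTable("x", {f"g{i}": 1.0 for i in range(10)})
        sets = classify_directional_sets(fc)
        assert sets.up == frozenset() and sets.down == frozenset()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            classify_directional_sets(FoldChangeTable("x", {}))

    @pytest.mark.parametrize("up, down", [(0.9, 0.5), (2.0, 1.5), (2.0, 0.0)])
    def test_invalid_cutoffs_rejected(self, up, down):
        with pytest.raises(ValueError):
            classify_directional_sets(FoldChangeTable("x", {"g": 1.0}), up, down)

    @given(
        st.dictionaries(
            st.text(alphabet="abcdefg", min_size=1, max_size=3),
            st.floats(min_value=1e-6, max_value=1e6),
            min_size=1,
            max_size=30,
        )
    )
    def test_partition_of_universe(self, entries):
        sets = classify_directional_sets(FoldChangeTable("h", entries))
        assert sets.up | sets.down | sets.unclassified == sets.universe
        assert not sets.up & sets.down
        assert not sets.up & sets.unclassified
        assert not sets.down & sets.unclassified


class TestAnalyticZscore:
    def test_closed_form_example(self):
        r = analytic_intersection_zscore(5, 8, 20, 4)
        assert r.null_mean == pytest.approx(2.0)
        assert r.null_sd == pytest.approx(0.97333, abs=1e-5)
        assert r.z == pytest.approx(2.0548, abs=1e-4)
        assert r.method == "analytic"

    @pytest.mark.parametrize("N, n1, n2", [(20, 5, 8), (50, 10, 30), (7, 3, 3)])
    def test_moments_match_exhaustive_enumeration(self, N, n1, n2):
        mean, var = hypergeometric_moments_by_enumeration(N, n1, n2)
        r = analytic_intersection_zscore(n1, n2, N, 0)
        assert abs(r.null_mean - float(mean)) < 1e-12
        assert abs(r.null_sd**2 - float(var)) < 1e-12

    def test_moments_match_scipy_hypergeom(self):
        r = analytic_intersection_zscore(5, 8, 20, 4)
        dist = stats.hypergeom(20, 5, 8)
        assert r.null_mean == pytest.approx(dist.mean(), abs=1e-12)
        assert r.null_sd == pytest.approx(dist.std(), abs=1e-12)

    @given(
        st.integers(min_value=2, max_value=200),
        st.data(),
    )
    def test_symmetric_in_set_order(self, N, data):
        n1 = data.draw(st.integers(min_value=0, max_value=N))
        n2 = data.draw(st.integers(min_value=0, max_value=N))
        k = data.draw(st.integers(min_value=0, max_value=min(n1, n2)))
        a = analytic_intersection_zscore(n1, n2, N, k)
        b = analytic_intersection_zscore(n2, n1, N, k)
        assert a.null_mean == b.null_mean
        assert a.null_sd == b.null_sd
        if not a.degenerate:
            assert a.z == pytest.approx(b.z)

    def test_empty_set_is_degenerate(self):
        r = analytic_intersection_zscore(0, 8, 20, 0)
        assert r.null_mean == 0 and r.degenerate and r.z is None

    def test_saturated_sets_are_degenerate(self):
        r = analytic_intersection_zscore(20, 20, 20, 20)
        assert r.null_mean == 20 and r.degenerate and r.z is None


UNIVERSE_20 = {f"g{i:02d}" for i in range(20)}


class TestMonteCarloZscore:
    def test_matches_analytic_oracle_on_small_universe(self):
        universe = sorted(UNIVERSE_20)
        setA = set(universe[:5])
        setB = set(universe[1:9])  # overlap 4
        n_mc = 100_000
        r = mc_intersection_zscore(setA, setB, universe, n_mc=n_mc, seed=7)
        exact = analytic_intersection_zscore(5, 8, 20, 4)
        # MC standard error of z: mean and sd estimation noise combined
        se = math.sqrt(1 / n_mc + exact.z**2 / (2 * (n_mc - 1)))
        assert r.k_observed == 4
        assert abs(r.z - exact.z) < 3 * se

    def test_self_similarity_is_positive(self):
        setA = {f"g{i:02d}" for i in range(5)}
        r = mc_intersection_zscore(setA, setA, UNIVERSE_20, n_mc=10_000, seed=1)
        assert r.z > 0
        assert r.k_observed == 5

    def test_reproducible_under_fixed_seed(self):
        a = mc_intersection_zscore({"g00"}, {"g00", "g01"}, UNIVERSE_20, 500, seed=3)
        b = mc_intersection_zscore({"g00"}, {"g00", "g01"}, UNIVERSE_20, 500, seed=3)
        c = mc_intersection_zscore({"g00"}, {"g00", "g01"}, UNIVERSE_20, 500, seed=4)
        assert (a.null_mean, a.null_sd, a.z) == (b.null_mean, b.null_sd, b.z)
        assert (a.null_mean, a.null_sd) != (c.null_mean, c.null_sd)

    def test_empty_set_reports_degenerate_not_number(self):
        r = mc_intersection_zscore(set(), {"g00"}, UNIVERSE_20, n_mc=100, seed=0)
        assert r.degenerate and r.z is None and r.null_sd == 0

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subsets"):
            mc_intersection_zscore({"zz"}, {"g00"}, UNIVERSE_20, n_mc=10, seed=0)

    def test_null_mean_converges_to_analytic(self):
        """MC null mean within 4 standard errors of n1*n2/N across 20 seeds."""
        N, n1, n2, n_mc = 200, 30, 50, 10_000
        universe = [f"g{i}" for i in range(N)]
        exact = analytic_intersection_zscore(n1, n2, N, 0)
        se = exact.null_sd / math.sqrt(n_mc)
        for seed in range(20):
            r = mc_intersection_zscore(
                universe[:n1], universe[N - n2:], universe, n_mc=n_mc, seed=seed
            )
            assert abs(r.null_mean - exact.null_mean) < 4 * se


class TestCompareConditions:
    def _table(self, label, values):
        return FoldChangeTable(label, values)

    def test_self_comparison_recovers_full_sets(self):
        rng = np.random.default_rng(5)
        entries = {f"g{i}": float(v) for i, v in enumerate(2.0 ** rng.normal(0, 1.2, 300))}
        t = self._table("same", entries)
        up, down = compare_conditions(t, t, n_mc=2000, seed=9)
        assert up.k_observed == up.n1 == up.n2
        assert down.k_observed == down.n1 == down.n2
        assert up.z > 0 and down.z > 0

    def test_universe_defaults_to_common_genes(self):
        t1 = self._table("a", {"g1": 3.0, "g2": 0.2, "g3": 1.0, "g5": 4.0})
        t2 = self._table("b", {"g1": 3.0, "g2": 0.2, "g3": 1.0, "g4": 4.0})
        up, down = compare_conditions(t1, t2, n_mc=100, seed=0)
        assert up.N == 3  # g1, g2, g3
        assert up.n1 == up.n2 == 1 and up.k_observed == 1
        assert down.n1 == down.n2 == 1 and down.k_observed == 1

    def test_union_universe_counts_all_genes(self):
        t1 = self._table("a", {"g1": 3.0, "g2": 0.2, "g3": 1.0, "g5": 4.0})
        t2 = self._table("b", {"g1": 3.0, "g2": 0.2, "g3": 1.0, "g4": 4.0})
        up, _ = compare_conditions(t1, t2, n_mc=100, seed=0, universe="union")
        assert up.N == 5
        assert up.n1 == 2  # g1 and g5

    def test_analytic_method_matches_closed_form(self):
        t1 = self._table("a", {"g1": 3.0, "g2": 0.2, "g3": 1.0, "g4": 0.1})
        t2 = self._table("b", {"g1": 3.0, "g2": 0.3, "g3": 1.0, "g4": 0.2})
        up, down = compare_conditions(t1, t2, method="analytic", seed=0)
        assert up.method == "analytic"
        assert up.null_mean == up.n1 * up.n2 / up.N
        assert down.null_mean == down.n1 * down.n2 / down.N

    def test_too_few_shared_genes_rejected(self):
        t1 = self._table("a", {"g1": 3.0, "gx": 2.0})
        t2 = self._table("b", {"g1": 3.0, "gy": 2.0})
        with pytest.raises(ValueError, match="at least 2"):
            compare_conditions(t1, t2, seed=0)
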