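"""Protein selection, quartile coding, Ward clustering, chi-square."""

import itertools

import numpy as np
import pandas as pd
import pytest

from panelomics.errors import InsufficientDataError, PanelomicsError
from panelomics.oncobiogram import ActivityProfile
from panelomics.proteome import (
    SensitivityCall,
    classify_sensitivity,
    cluster_response_chi2,
    compare_proteins,
    cut_tree,
    dendrogram_to_newick,
    quartile_code,
    select_top,
    ward_cluster,
)
from panelomics.synth import GeneratorConfig, gen_activity, gen_panel, gen_proteome

LINES = [f"C{i:02d}" for i in range(10)]


def _profile(values, lines=LINES):
    return ActivityProfile("p", dict(zip(lines, values)))


def ward_oracle(data):
    """Exhaustive Ward: at every step recompute, for every cluster pair,
    the increase in total within-cluster sum of squares from merging,
    and merge the minimum. Heights reported as sqrt(2 * delta-ESS),
    which is the scale agglomerative Ward linkage uses (for singletons
    it reduces to the Euclidean distance)."""
    clusters = [[i] for i in range(data.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for (i, a), (j, b) in itertools.combinations(enumerate(clusters), 2):
            merged = data[a + b]
            ess_merged = ((merged - merged.mean(axis=0)) ** 2).sum()
            ess_a = ((data[a] - data[a].mean(axis=0)) ** 2).sum()
            ess_b = ((data[b] - data[b].mean(axis=0)) ** 2).sum()
            delta = ess_merged - ess_a - ess_b
            if best is None or delta < best[0]:
                best = (delta, i, j)
        delta, i, j = best
        heights.append(np.sqrt(2.0 * delta))
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


class TestCompareProteins:
    def test_identical_and_negated_features(self, rng):
        vals = rng.standard_normal(10)
        prof = _profile(vals)
        matrix = pd.DataFrame(
            [vals, -vals], index=["same", "anti"], columns=LINES
        )
        results, skipped = compare_proteins(prof, matrix)
        assert not skipped
        by_id = dict(results)
        assert by_id["same"].r == pytest.approx(1.0)
        assert by_id["anti"].r == pytest.approx(-1.0)

    def test_planted_features_occupy_extreme_ranks(self):
        cfg = GeneratorConfig(seed=0)
        panel = gen_panel(cfg)
        prof, _, _ = gen_activity(cfg, panel)
        matrix, direct, inverse = gen_proteome(cfg, prof)
        results, _ = compare_proteins(prof, matrix)
        ranked = sorted(results, key=lambda t: -t[1].r)
        top = {f for f, _ in ranked[:25]}
        bottom = {f for f, _ in ranked[-25:]}
        assert len(top & set(direct)) >= 18
        assert len(bottom & set(inverse)) >= 18

    def test_no_overlap_raises(self, rng):
        prof = _profile(rng.standard_normal(10))
        matrix = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"],
                              columns=["X1", "X2", "X3"])
        with pytest.raises(PanelomicsError):
            compare_proteins(prof, matrix)


class TestSelectTop:
    def test_default_sizes_disjoint(self):
        cfg = GeneratorConfig(seed=1)
        panel = gen_panel(cfg)
        prof, _, _ = gen_activity(cfg, panel)
        matrix, _, _ = gen_proteome(cfg, prof)
        results, _ = compare_proteins(prof, matrix)
        sel = select_top(results)
        assert len(sel.direct) == 20 and len(sel.inverse) == 20
        assert not set(f for f, _ in sel.direct) & set(f for f, _ in sel.inverse)
        assert all(r > 0 for _, r in sel.direct)
        assert all(r < 0 for _, r in sel.inverse)

    def test_zero_sizes_give_empty_selection(self, rng):
        prof = _profile(rng.standard_normal(10))
        matrix = pd.DataFrame(
            rng.standard_normal((5, 10)), columns=LINES,
            index=[f"f{i}" for i in range(5)],
        )
        results, _ = compare_proteins(prof, matrix)
        sel = select_top(results, k_direct=0, k_inverse=0)
        assert sel.direct == () and sel.inverse == ()

    def test_order_invariance(self, rng):
        prof = _profile(rng.standard_normal(10))
        matrix = pd.DataFrame(
            rng.standard_normal((30, 10)), columns=LINES,
            index=[f"f{i}" for i in range(30)],
        )
        results, _ = compare_proteins(prof, matrix)
        sel1 = select_top(results, k_direct=5, k_inverse=5)
        sel2 = select_top(results[::-1], k_direct=5, k_inverse=5)
        assert sel1 == sel2

    def test_shortfall_raises_with_count(self, rng):
        prof = _profile(rng.standard_normal(10))
        vals = np.vstack([prof.vector(LINES) + 0.01 * rng.standard_normal(10)
                          for _ in range(3)])
        matrix = pd.DataFrame(vals, columns=LINES, index=["a", "b", "c"])
        results, _ = compare_proteins(prof, matrix)
        with pytest.raises(InsufficientDataError, match="negatively"):
            select_top(results, k_direct=1, k_inverse=2)


class TestQuartileCode:
    def test_five_point_example(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["f"],
                              columns=list("abcde"))
        codes = quartile_code(matrix).loc["f"].tolist()
        assert codes == ["Q1", "Q2", "MEDIAN", "Q3", "Q4"]

    def test_constant_feature_all_median(self):
        matrix = pd.DataFrame([[2.0] * 6], index=["f"], columns=list("abcdef"))
        assert (quartile_code(matrix).loc["f"] == "MEDIAN").all()

    def test_balanced_bins_on_distinct_length9(self, rng):
        """For distinct-valued vectors of length 4k+1, the median takes
        one value and the four bins split the rest evenly (counts differ
        by <= 1); checked by brute force over random permutations."""
        base = np.arange(9, dtype=float) * 1.7 + 0.3
        for _ in range(50):
            perm = rng.permutation(base)
            matrix = pd.DataFrame([perm], index=["f"],
                                  columns=[f"c{i}" for i in range(9)])
            counts = quartile_code(matrix).loc["f"].value_counts()
            assert counts.get("MEDIAN", 0) == 1
            quarts = [counts.get(q, 0) for q in ("Q1", "Q2", "Q3", "Q4")]
            assert max(quarts) - min(quarts) <= 1

    def test_matrix_equals_featurewise(self, rng):
        matrix = pd.DataFrame(
            rng.standard_normal((6, 9)),
            index=[f"f{i}" for i in range(6)],
            columns=[f"c{i}" for i in range(9)],
        )
        whole = quartile_code(matrix, axis="per_feature")
        for f in matrix.index:
            row = quartile_code(matrix.loc[[f]], axis="per_feature")
            assert (whole.loc[f] == row.loc[f]).all()

    def test_too_few_values_raise(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"],
                              columns=list("abc"))
        with pytest.raises(InsufficientDataError):
            quartile_code(matrix)


class TestWardCluster:
    def test_identical_items_merge_at_zero(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0]] * 2, index=["a", "b"],
                              columns=list("xyz"))
        tree = ward_cluster(matrix, zscore=False)
        assert tree.shape == (1, 4)
        assert tree[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_tight_pairs_merge_first(self):
        data = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
        matrix = pd.DataFrame(data, index=list("abcd"), columns=["u", "v"])
        tree = ward_cluster(matrix, zscore=False)
        first_two = {frozenset(tree[0, :2].astype(int)),
                     frozenset(tree[1, :2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_matches_exhaustive_variance_oracle(self, rng):
        """Agglomerative Ward merge heights equal exhaustive
        recomputation of cluster variances at each step, to 1e-9."""
        for _ in range(10):
            data = rng.standard_normal((8, 5))
            matrix = pd.DataFrame(data, index=[f"i{k}" for k in range(8)],
                                  columns=[f"c{k}" for k in range(5)])
            tree = ward_cluster(matrix, zscore=False)
            np.testing.assert_allclose(tree[:, 2], ward_oracle(data), atol=1e-9)

    def test_heights_monotone_nondecreasing(self, rng):
        for _ in range(10):
            matrix = pd.DataFrame(
                rng.standard_normal((12, 4)),
                index=[f"i{k}" for k in range(12)],
                columns=list("wxyz"),
            )
            tree = ward_cluster(matrix)
            assert np.all(np.diff(tree[:, 2]) >= -1e-12)

    def test_all_missing_item_raises(self):
        matrix = pd.DataFrame([[np.nan] * 3, [1.0, 2.0, 3.0]],
                              index=["bad", "ok"], columns=list("xyz"))
        with pytest.raises(PanelomicsError):
            ward_cluster(matrix, zscore=False)


class TestCutTree:
    @pytest.fixture()
    def pair_tree(self):
        data = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
        matrix = pd.DataFrame(data, index=list("abcd"), columns=["u", "v"])
        return ward_cluster(matrix, zscore=False)

    def test_k_equals_n_gives_singletons(self, pair_tree):
        assignment = cut_tree(pair_tree, 4, list("abcd"))
        assert sorted(assignment.values()) == [1, 2, 3, 4]

    def test_k_one_single_cluster(self, pair_tree):
        assert set(cut_tree(pair_tree, 1, list("abcd")).values()) == {1}

    def test_two_pairs_recovered(self, pair_tree):
        assignment = cut_tree(pair_tree, 2, list("abcd"))
        assert assignment["a"] == assignment["b"] == 1
        assert assignment["c"] == assignment["d"] == 2

    def test_out_of_range_raises(self, pair_tree):
        with pytest.raises(PanelomicsError):
            cut_tree(pair_tree, 5, list("abcd"))

    def test_newick_export_parses(self, pair_tree):
        import dendropy

        nwk = dendrogram_to_newick(pair_tree, list("abcd"))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set("abcd")


class TestSensitivityAndChi2:
    def test_odd_panel_median_split(self):
        prof = ActivityProfile("p", {"a": -6.0, "b": -5.0, "c": -4.0})
        call = classify_sensitivity(prof)
        assert call.calls == {"a": "sensitive", "b": "tie", "c": "resistant"}

    def test_all_equal_all_tie(self):
        prof = ActivityProfile("p", {"a": -5.0, "b": -5.0, "c": -5.0})
        assert set(classify_sensitivity(prof).calls.values()) == {"tie"}

    def test_even_panel_median_split(self):
        prof = ActivityProfile("p", {"a": -7.0, "b": -6.0, "c": -5.0, "d": -4.0})
        call = classify_sensitivity(prof)
        assert call.threshold == pytest.approx(-5.5)
        assert call.calls == {"a": "sensitive", "b": "sensitive",
                              "c": "resistant", "d": "resistant"}

    def test_balanced_table_statistic_zero(self):
        clusters = {f"l{i}": 1 + i // 10 for i in range(20)}
        calls_map = {f"l{i}": ("sensitive" if i % 2 else "resistant")
                     for i in range(20)}
        call = SensitivityCall(calls=calls_map, threshold=0.0)
        res = cluster_response_chi2(clusters, call)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_perfect_separation_closed_form(self):
        """[[10,0],[0,10]]: all expected counts are 5, so the statistic
        is sum (O-E)^2/E = 4 * 25/5 = 20 on 1 df."""
        clusters = {f"l{i}": 1 + i // 10 for i in range(20)}
        calls_map = {f"l{i}": ("sensitive" if i < 10 else "resistant")
                     for i in range(20)}
        call = SensitivityCall(calls=calls_map, threshold=0.0)
        res = cluster_response_chi2(clusters, call)
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_ties_are_excluded(self):
        prof = ActivityProfile(
            "p", {"a": -6.0, "b": -5.0, "c": -4.0, "d": -6.5, "e": -3.5}
        )
        call = classify_sensitivity(prof)  # median -5 -> b is a tie
        clusters = {"a": 1, "b": 1, "c": 2, "d": 1, "e": 2}
        res = cluster_response_chi2(clusters, call)
        assert int(res.table.values.sum()) == 4

    def test_single_cluster_raises(self):
        prof = ActivityProfile("p", {"a": -6.0, "b": -4.0, "c": -5.9, "d": -4.1})
        call = classify_sensitivity(prof)
        with pytest.raises(PanelomicsError):
            cluster_response_chi2({k: 1 for k in "abcd"}, call)
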