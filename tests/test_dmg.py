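"""Pairwise DMG calling, taxonomy, impact/overlap scores, pseudo-cells."""

import numpy as np
import pandas as pd
import pytest

from methylatlas.dmg import (
    build_taxonomy,
    enforce_min_dmg,
    impact_scores,
    match_clusters,
    overlap_score,
    pairwise_dmg,
    pseudo_cell_aggregate,
    top_markers,
    total_impact,
)


def _two_cluster_values(rng, n=50, n_genes=5, hypo_gene=0, delta=1.3):
    """Cluster 0 hypo-methylated at one gene; others identical."""
    values = rng.normal(1.0, 0.05, (2 * n, n_genes))
    labels = np.repeat([0, 1], n)
    values[labels == 0, hypo_gene] -= delta
    return values, labels


class TestPairwiseDmg:
    def test_planted_hypo_gene_significant_with_auroc_one(self, rng):
        values, labels = _two_cluster_values(rng)
        tab = pairwise_dmg(values, labels)
        rec = tab[(tab.gene == "gene_0") & (tab.cluster_a == 0)].iloc[0]
        assert rec.significant
        assert rec.auroc == pytest.approx(1.0)
        assert rec.delta < -0.5
        # the reverse direction is not hypo in cluster 1
        rev = tab[(tab.gene == "gene_0") & (tab.cluster_a == 1)].iloc[0]
        assert not rev.significant

    def test_identical_distributions_not_significant(self, rng):
        values = rng.normal(1.0, 0.05, (100, 4))
        labels = np.repeat([0, 1], 50)
        tab = pairwise_dmg(values, labels)
        assert not tab.significant.any()

    def test_delta_boundary_is_strict(self):
        # constant levels differing by exactly 0.5: delta == -0.5 excluded
        values = np.zeros((40, 1))
        labels = np.repeat([0, 1], 20)
        values[labels == 0, 0] = 0.5
        values[labels == 1, 0] = 1.0
        tab = pairwise_dmg(values, labels)
        rec = tab[(tab.cluster_a == 0)].iloc[0]
        assert rec.delta == -0.5
        assert not rec.significant

    def test_constant_gene_p_one_auroc_half(self):
        values = np.ones((20, 1))
        labels = np.repeat([0, 1], 10)
        tab = pairwise_dmg(values, labels)
        assert (tab.p == 1.0).all()
        assert (tab.auroc == 0.5).all()

    def test_type_one_control_on_null(self, rng):
        values = rng.normal(1.0, 0.2, (200, 100))
        labels = np.repeat([0, 1], 100)
        tab = pairwise_dmg(values, labels)
        assert tab.significant.mean() < 0.001

    def test_requires_two_cells_per_cluster(self, rng):
        values = rng.normal(size=(3, 2))
        with pytest.raises(ValueError, match="< 2 cells"):
            pairwise_dmg(values, np.array([0, 0, 1]))


class TestEnforceMinDmg:
    def test_artificially_split_cluster_merged(self, rng):
        # two genuine clusters, one split in half arbitrarily -> halves merge
        values, labels = _two_cluster_values(rng, n=60, n_genes=8, delta=1.5)
        for g in range(1, 6):
            values[labels == 1, g] -= 1.5
        split = labels.copy()
        split[np.where(labels == 0)[0][:30]] = 2  # fake subdivision
        pcs = values.copy()
        merged, dmgs = enforce_min_dmg(split, values, pcs, min_dmg=5)
        assert len(set(merged)) == 2
        # the two genuine clusters survive distinct
        assert len(set(merged[labels == 0])) == 1
        assert len(set(merged[labels == 1])) == 1

    def test_well_separated_clusters_unchanged(self, rng):
        values, labels = _two_cluster_values(rng, n=50, n_genes=10, delta=1.5)
        for g in range(5):
            values[labels == 0, g] -= 1.5
        for g in range(5, 10):
            values[labels == 1, g] -= 1.5
        merged, _ = enforce_min_dmg(labels.copy(), values, values, min_dmg=5)
        assert np.array_equal(merged, labels)


class TestTaxonomy:
    def _three_subtype_values(self, rng):
        # subtypes 0 and 1 share a hypo program; 2 is distant
        n, n_genes = 40, 30
        values = rng.normal(1.0, 0.05, (3 * n, n_genes))
        labels = np.repeat([0, 1, 2], n)
        values[np.isin(labels, [0, 1])][:, :10] -= 0  # noop, clarity
        values[labels != 2, :10] -= 1.2  # shared program in 0 and 1
        values[labels == 1, 10:14] -= 1.2  # private program in 1
        values[labels == 2, 14:24] -= 1.2  # private program in 2
        return values, labels

    def test_shared_program_subtypes_are_siblings(self, rng):
        values, labels = self._three_subtype_values(rng)
        dmgs = pairwise_dmg(values, labels)
        tree = build_taxonomy(values, dmgs, labels)
        root = max(tree.nodes(), key=lambda n: n[1])
        sides = {frozenset(root[2]), frozenset(root[3])}
        assert frozenset({0, 1}) in sides and frozenset({2}) in sides

    def test_duplicate_profiles_join_at_zero_height(self, rng):
        values, labels = self._three_subtype_values(rng)
        values[labels == 1] = values[labels == 0]  # make 1 a copy of 0
        dmgs = pairwise_dmg(values, labels)
        tree = build_taxonomy(values, dmgs, labels)
        lowest = min(node[1] for node in tree.nodes())
        assert lowest == pytest.approx(0.0, abs=1e-12)

    def test_marker_union_deduplicated(self, rng):
        values, labels = self._three_subtype_values(rng)
        dmgs = pairwise_dmg(values, labels)
        genes = top_markers(dmgs, top_n=50)
        assert len(genes) == len(set(genes))

    def test_newick_export_contains_all_leaves(self, rng):
        values, labels = self._three_subtype_values(rng)
        dmgs = pairwise_dmg(values, labels)
        tree = build_taxonomy(values, dmgs, labels)
        nwk = tree.to_newick()
        assert nwk.endswith(");")
        for leaf in (0, 1, 2):
            assert str(leaf) in nwk


def _manual_tree(heights=(1.0, 0.5)):
    """Taxonomy over 3 leaves: (0,1) join at heights[1], +2 at heights[0]."""
    from methylatlas.dmg import TaxonomyTree

    z = np.array(
        [[0.0, 1.0, heights[1], 2.0], [2.0, 3.0, heights[0], 3.0]]
    )
    profile = pd.DataFrame(np.zeros((3, 2)), index=["a", "b", "c"])
    return TaxonomyTree(linkage_matrix=z, leaf_names=["a", "b", "c"], profile=profile)


def _sig_table(rows):
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "item"])


class TestImpactScores:
    def test_full_impact_is_one(self):
        # root: A = {a, b} (M=2) vs B = {c} (N=1)? build M=3 x N=4 case below
        from methylatlas.dmg import TaxonomyTree

        # manual two-branch tree with 3 + 4 leaves
        #   leaves 0..2 -> left, 3..6 -> right
        z = np.array(
            [
                [0, 1, 0.1, 2], [7, 2, 0.2, 3],          # left branch (node 7, 8)
                [3, 4, 0.1, 2], [9, 5, 0.15, 3], [10, 6, 0.2, 4],  # right (9..11)
                [8, 11, 1.0, 7],
            ]
        )
        names = list("ABCDEFG")
        tree = TaxonomyTree(z, names, pd.DataFrame(np.zeros((7, 1)), index=names))
        rows = [(x, y, "gene") for x in "ABC" for y in "DEFG"]
        imp = impact_scores(tree, _sig_table(rows))
        root = imp[imp.height == 1.0].iloc[0]
        assert (root.a, root.b, root.M, root.N) == (12, 0, 3, 4)
        assert root.IS_A == 1.0

    def test_balanced_significance_is_zero(self):
        tree = _manual_tree()
        rows = [("a", "c", "g"), ("c", "a", "g")]
        imp = impact_scores(tree, _sig_table(rows))
        root = imp[imp.height == 1.0].iloc[0]
        assert root.IS_A == 0.0

    def test_printed_formula_half(self):
        # M=2, N=3, a=4, b=1 -> IS_A = 0.5; brute-force counting oracle
        from methylatlas.dmg import TaxonomyTree

        z = np.array(
            [[0, 1, 0.2, 2], [2, 3, 0.1, 2], [6, 4, 0.3, 3], [5, 7, 1.0, 5]]
        )
        names = list("abcde")
        tree = TaxonomyTree(z, names, pd.DataFrame(np.zeros((5, 1)), index=names))
        rows = [("a", "c", "g"), ("a", "d", "g"), ("b", "c", "g"),
                ("b", "e", "g"), ("c", "a", "g")]
        imp = impact_scores(tree, _sig_table(rows))
        root = imp[imp.height == 1.0].iloc[0]
        # oracle: direct count over the leaf bipartition
        left, right = {"a", "b"}, {"c", "d", "e"}
        a = sum(1 for x, y, _ in rows if x in left and y in right)
        b = sum(1 for x, y, _ in rows if x in right and y in left)
        assert (a, b) == (4, 1)
        assert root.IS_A == pytest.approx((a - b) / 6) == pytest.approx(0.5)

    def test_antisymmetry_exact(self, rng):
        tree = _manual_tree()
        rows = [
            (x, y, f"g{k}")
            for k in range(5)
            for x, y in [("a", "c"), ("b", "c"), ("c", "b")]
            if rng.random() < 0.6
        ]
        if not rows:
            rows = [("a", "c", "g0")]
        imp = impact_scores(tree, _sig_table(rows))
        assert np.array_equal(imp.IS_B.to_numpy(), -imp.IS_A.to_numpy())


class TestTotalImpact:
    def test_height_weighted_sum(self):
        tree = _manual_tree(heights=(1.0, 0.5))
        # item with |IS_A| = 1 at root (a-b = 2 over M*N = 2) and 0.4 at low node
        imp = pd.DataFrame(
            {
                "node": [4, 3],
                "height": [1.0, 0.5],
                "item": ["g", "g"],
                "a": [2, 1], "b": [0, 0], "M": [2, 1], "N": [1, 1],
                "IS_A": [1.0, 0.4], "IS_B": [-1.0, -0.4],
            }
        )
        assert total_impact(imp)["g"] == pytest.approx(1.2)

    def test_never_significant_item_zero(self):
        tree = _manual_tree()
        imp = impact_scores(tree, _sig_table([("a", "c", "g1")]))
        extra = imp.copy()
        extra["item"] = "g2"
        extra[["a", "b", "IS_A", "IS_B"]] = 0
        ti = total_impact(pd.concat([imp, extra]))
        assert ti["g2"] == 0.0
        assert ti["g1"] > 0

    def test_subtree_restriction(self):
        imp = pd.DataFrame(
            {
                "node": [4, 3], "height": [1.0, 0.5], "item": ["g", "g"],
                "a": [1, 1], "b": [0, 0], "M": [1, 1], "N": [1, 1],
                "IS_A": [1.0, 1.0], "IS_B": [-1.0, -1.0],
            }
        )
        assert total_impact(imp, nodes=[3])["g"] == pytest.approx(0.5)


class TestOverlapScore:
    def test_identical_partitions_score_one(self):
        labels = np.repeat([0, 1, 2], 40)
        os = overlap_score(labels, labels, labels)
        assert np.allclose(np.diag(os.to_numpy()), 1.0)
        assert os.to_numpy().sum() == pytest.approx(3.0)  # off-diagonal zero

    def test_hand_evaluated_half(self):
        # a1 = {1,2,3,4}, b1 = {1,2}; co-clusters {1,2} and {3,4}
        labels_a = ["a1", "a1", "a1", "a1"]
        labels_b = ["b1", "b1", "b2", "b2"]
        co = ["co1", "co1", "co2", "co2"]
        os = overlap_score(labels_a, labels_b, co)
        assert os.loc["a1", "b1"] == pytest.approx(0.5)

    def test_no_shared_co_cluster_scores_zero(self):
        labels_a = ["a1", "a1", "a2", "a2"]
        labels_b = ["b1", "b1", "b2", "b2"]
        co = ["x", "x", "y", "y"]
        os = overlap_score(labels_a, labels_b, co)
        assert os.loc["a1", "b2"] == 0.0

    def test_scores_bounded(self, rng):
        a = rng.integers(0, 4, 200)
        b = rng.integers(0, 3, 200)
        co = rng.integers(0, 5, 200)
        os = overlap_score(a, b, co).to_numpy()
        assert (os >= 0).all() and (os <= 1 + 1e-12).all()

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            overlap_score([0, 1], [0, 1, 2], [0, 1, 2])

    def test_match_above_threshold_else_top(self):
        os = pd.DataFrame(
            [[0.6, 0.25], [0.2, 0.28]], index=["m1", "m2"], columns=["a1", "a2"]
        )
        matches = match_clusters(os, threshold=0.3)
        assert matches["m1"] == ["a1"]
        assert matches["m2"] == ["a2"]  # nothing above 0.3 -> top ranked


class TestPseudoCells:
    def test_hundred_cell_cluster_gives_two_pseudocells(self, small_cohort, rng):
        counts, _ = small_cohort
        sub = counts.subset(cells=np.arange(100))
        labels = np.zeros(100, dtype=int)
        agg, mapping = pseudo_cell_aggregate(sub, labels, seed=0)
        assert agg.n_cells == 2

    def test_small_cluster_dropped_with_warning(self, small_cohort):
        counts, _ = small_cohort
        sub = counts.subset(cells=np.arange(9))
        with pytest.warns(UserWarning, match="< 10 cells"):
            agg, _ = pseudo_cell_aggregate(sub, np.zeros(9, dtype=int))
        assert agg.n_cells == 0

    def test_counts_conserved_over_retained_groups(self, small_cohort):
        counts, truth = small_cohort
        agg, mapping = pseudo_cell_aggregate(counts, truth.cell_cluster, seed=0)
        kept = mapping["pseudo_cell"].to_numpy() >= 0
        for ctx in counts.contexts:
            assert agg.mc[ctx].sum() == counts.mc[ctx][kept].sum()
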