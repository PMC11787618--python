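"""Neighbor joining, Robinson-Foulds, and Newick round-trips."""

import numpy as np
import pytest

import dendropy
from dendropy.calculate import treecompare

from helpers import adjacency_to_newick, newick_splits, path_distances, random_binary_tree
from synortho.phylo import (
    DistanceMatrix,
    distances_from_msa,
    nj_tree,
    read_newick,
    rf_distance,
    write_newick,
)
from synortho.msa import MSA, align_family
from synortho.synthetic import SimulationConfig, simulate


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[1, 1], [1, 0]]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]]))


class TestNJ:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        # three-point formulas: la=(5+9-10)/2=2, lb=(5+10-9)/2=3, lc=(9+10-5)/2=7
        assert lengths == pytest.approx({"a": 2.0, "b": 3.0, "c": 7.0})

    def test_additive_four_taxon_matrix_recovers_tree(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive path distances
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(labels, d))
        expected = read_newick("((a:1,b:2):0.5,(c:3,d:4):0.5);")
        assert rf_distance(tree, expected) == 0

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_consistency_on_random_additive_matrices(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(6):
            labels = [f"t{i}" for i in range(n_leaves)]
            adj = random_binary_tree(labels, rng)
            d = path_distances(adj, labels)
            tree = nj_tree(DistanceMatrix(labels, d))
            truth = read_newick(adjacency_to_newick(adj))
            assert rf_distance(tree, truth) == 0

    def test_generating_tree_recovered_from_family(self):
        newick = "((NPV00:0.4,NPV01:0.4):0.6,(NPV02:0.4,NPV03:0.4):0.6,NPV04:1.0);"
        cfg = SimulationConfig(n_genomes=5, seed=9, tree=newick, divergence=0.12)
        genomes, truth = simulate(cfg)
        members = [
            (g.genome_id, g.gene(truth.genomes[g.genome_id].member_gene).protein)
            for g in genomes
        ]
        msa = align_family(members)
        tree = nj_tree(distances_from_msa(msa))
        assert rf_distance(tree, read_newick(newick)) == 0

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestRF:
    def test_identical_trees_have_zero_distance(self):
        t = read_newick("((a,b),(c,d),e);")
        assert rf_distance(t, read_newick("((a,b),(c,d),e);")) == 0

    def test_two_distinct_quartets_differ_by_two(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rf_distance(read_newick("((a,b),(c,d));"), read_newick("((a,b),(c,e));"))

    def test_matches_brute_force_split_comparison(self):
        rng = np.random.default_rng(17)
        labels = [f"t{i}" for i in range(6)]
        for _ in range(20):
            n1 = adjacency_to_newick(random_binary_tree(labels, rng))
            n2 = adjacency_to_newick(random_binary_tree(labels, rng))
            expected = len(newick_splits(n1) ^ newick_splits(n2))
            assert rf_distance(read_newick(n1), read_newick(n2)) == expected

    def test_agrees_with_dendropy(self):
        rng = np.random.default_rng(23)
        labels = [f"t{i}" for i in range(7)]
        ns = dendropy.TaxonNamespace()
        for _ in range(10):
            n1 = adjacency_to_newick(random_binary_tree(labels, rng))
            n2 = adjacency_to_newick(random_binary_tree(labels, rng))
            d1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=ns)
            d2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=ns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = treecompare.symmetric_difference(d1, d2)
            assert rf_distance(read_newick(n1), read_newick(n2)) == expected

    def test_metric_properties_on_random_trees(self):
        rng = np.random.default_rng(31)
        labels = [f"t{i}" for i in range(6)]
        trees = [read_newick(adjacency_to_newick(random_binary_tree(labels, rng))) for _ in range(4)]
        for t1 in trees:
            assert rf_distance(t1, t1) == 0
            for t2 in trees:
                assert rf_distance(t1, t2) == rf_distance(t2, t1) >= 0


class TestNewickIO:
    def test_roundtrip_preserves_topology_and_lengths(self):
        rng = np.random.default_rng(8)
        labels = [f"t{i}" for i in range(5)]
        for _ in range(3):
            newick = adjacency_to_newick(random_binary_tree(labels, rng))
            tree = read_newick(newick)
            back = read_newick(write_newick(tree))
            assert rf_distance(tree, back) == 0
            orig = {
                leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
            }
            round_ = {
                leaf.taxon.label: leaf.edge.length for leaf in back.leaf_node_iter()
            }
            assert round_ == pytest.approx(orig)

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError):
            read_newick("((a,b),(c,d);")


class TestDistancesFromMSA:
    def test_pairwise_deletion_ignores_gap_columns(self):
        msa = MSA([("a", "AC-E"), ("b", "ACDE"), ("c", "GCDE")])
        dm = distances_from_msa(msa)
        i, j = dm.labels.index("a"), dm.labels.index("b")
        assert dm.d[i, j] == pytest.approx(0.0)  # 3 compared, 3 identical
        k = dm.labels.index("c")
        assert dm.d[j, k] == pytest.approx(0.25)

    def test_poisson_correction_monotone(self):
        msa = MSA([("a", "AAAA"), ("b", "AAAC"), ("c", "ACCC")])
        plain = distances_from_msa(msa, poisson=False)
        corr = distances_from_msa(msa, poisson=True)
        assert corr.d[0, 1] > plain.d[0, 1]
        assert corr.d[0, 2] > corr.d[0, 1]
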