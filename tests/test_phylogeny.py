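"""Concatenation, neighbor joining, bootstrap and newick round-trips."""

import itertools
import random

import numpy as np
import pytest

from mitocompare import (DistanceMatrix, GeneAlignment, PhyloTree, TreeNode,
                         bootstrap_support, concatenate, k2p_matrix,
                         neighbor_joining, newick_to_tree, nj_tree,
                         read_newick, root_with_outgroup, tree_to_newick,
                         write_newick)


# ---------------------------------------------------------------------------
# random additive trees: the oracle for NJ correctness
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n_leaves):
    """Random binary topology with positive lengths; returns (root, leaves)."""
    nodes = [TreeNode(name=f"L{i}", length=rng.uniform(0.1, 2.0))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(TreeNode(children=[a, b],
                              length=rng.uniform(0.1, 2.0)))
    return TreeNode(children=nodes)


def path_distance_matrix(root):
    """Leaf-to-leaf path-sum distances (the additivity oracle)."""
    paths = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(root, [])
    taxa = sorted(paths)
    n = len(taxa)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pa, pb = paths[taxa[i]], paths[taxa[j]]
        k = 0
        while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
            k += 1
        d = sum(x.length for x in pa[k:]) + sum(x.length for x in pb[k:])
        m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa=taxa, matrix=m)


def bipartitions_of(root):
    return PhyloTree(root=root).bipartitions()


class TestConcatenate:
    def test_two_blocks_partition_map(self):
        a = GeneAlignment("g1", {"x": "A" * 10, "y": "C" * 10})
        b = GeneAlignment("g2", {"x": "G" * 10, "y": "T" * 10})
        cat = concatenate({"g1": a, "g2": b}, ["g1", "g2"])
        assert cat.length == 20
        assert cat.partitions == {"g1": (1, 10), "g2": (11, 20)}
        assert cat.sequences["x"] == "A" * 10 + "G" * 10

    def test_order_independence_of_inputs(self, default_clade):
        genes = ["ND1", "ND2", "COI"]
        alns = {g: default_clade.alignments[g] for g in genes}
        shuffled = dict(reversed(list(alns.items())))
        c1 = concatenate(alns, genes)
        c2 = concatenate(shuffled, genes)
        assert c1.sequences == c2.sequences and c1.partitions == c2.partitions

    def test_total_length_is_sum_of_parts(self, default_clade):
        genes = [f.name for f in
                 next(iter(default_clade.genomes.values())).features
                 if f.ftype in ("PCG", "rRNA")]
        cat = concatenate({g: default_clade.alignments[g] for g in genes},
                          genes)
        assert cat.length == sum(default_clade.alignments[g].length
                                 for g in genes)
        assert len(genes) == 15

    def test_missing_taxon_needs_padding_flag(self):
        a = GeneAlignment("g1", {"x": "AAAA", "y": "CCCC"})
        b = GeneAlignment("g2", {"x": "GGGG", "y": "TTTT", "z": "AAAA"})
        with pytest.raises(ValueError):
            concatenate({"g1": a, "g2": b}, ["g1", "g2"])
        cat = concatenate({"g1": a, "g2": b}, ["g1", "g2"], pad_missing=True)
        assert cat.sequences["z"] == "----AAAA"


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], m))
        lengths = {c.name: c.length for c in tree.root.children}
        # l_A = (3+4-5)/2 = 1, l_B = (3+5-4)/2 = 2, l_C = (4+5-3)/2 = 3
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxon_additive_exact_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)); distances by path sums
        m = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], m))
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        assert tree.clamped_deficit == 0.0
        lengths = {}

        def collect(node):
            if node.is_leaf:
                lengths[node.name] = node.length
            for c in node.children:
                collect(c)

        collect(tree.root)
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    @pytest.mark.parametrize("n_leaves", [4, 6, 9, 12])
    def test_recovers_random_additive_trees(self, n_leaves):
        # property: NJ is exact on additive matrices
        rng = random.Random(100 + n_leaves)
        for _ in range(5):
            true = random_additive_tree(rng, n_leaves)
            dm = path_distance_matrix(true)
            est = neighbor_joining(dm)
            assert est.bipartitions() == bipartitions_of(true)
            assert est.clamped_deficit == pytest.approx(0.0, abs=1e-9)
            # reconstructed matrix equals the input (additivity both ways)
            back = path_distance_matrix(est.root)
            np.testing.assert_allclose(back.matrix, dm.matrix, atol=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"],
                                            np.array([[0, 1], [1, 0]], float)))

    def test_determinism_byte_identical(self):
        rng = random.Random(9)
        dm = path_distance_matrix(random_additive_tree(rng, 8))
        t1, t2 = neighbor_joining(dm), neighbor_joining(dm)
        assert tree_to_newick(t1) == tree_to_newick(t2)


class TestBootstrap:
    def test_same_seed_identical_supports(self, default_clade):
        genes = ["ND1", "ND2", "COI", "Cytb"]
        cat = concatenate({g: default_clade.alignments[g] for g in genes},
                          genes)
        t1 = bootstrap_support(cat, 30, seed=5)
        t2 = bootstrap_support(cat, 30, seed=5)
        assert tree_to_newick(t1) == tree_to_newick(t2)
        assert t1.effective_replicates == 30

    def test_deep_split_fully_supported(self, default_clade):
        genes = [f.name for f in
                 next(iter(default_clade.genomes.values())).features
                 if f.ftype in ("PCG", "rRNA")]
        cat = concatenate({g: default_clade.alignments[g] for g in genes},
                          genes)
        tree = bootstrap_support(cat, 100, seed=2)
        supports = []

        def collect(node):
            if node.support is not None:
                supports.append(node.support)
            for c in node.children:
                collect(c)

        collect(tree.root)
        assert supports and min(supports) >= 95

    def test_degenerate_alignment_supports_undefined(self):
        cat = concatenate(
            {"g": GeneAlignment("g", {t: "ACGT" * 25 for t in "abcd"})}, ["g"])
        tree = bootstrap_support(cat, 10, seed=0)
        assert all(n.support is None
                   for n in _all_nodes(tree.root) if not n.is_leaf)


def _all_nodes(node):
    yield node
    for c in node.children:
        yield from _all_nodes(c)


class TestNewick:
    def test_three_leaf_round_trip_canonical(self, tmp_path):
        t = newick_to_tree("(A:1,B:2,C:3);")
        p = tmp_path / "t.nwk"
        write_newick(t, p, precision=0)
        assert p.read_text().strip() == "(A:1,B:2,C:3);"

    def test_supports_serialized_as_internal_labels(self):
        inner = TreeNode(children=[TreeNode(name="A", length=1.0),
                                   TreeNode(name="B", length=1.0)],
                         support=97.0, length=0.5)
        t = PhyloTree(root=TreeNode(children=[inner,
                                              TreeNode(name="C", length=2.0)]))
        s = tree_to_newick(t, precision=1)
        assert s == "((A:1.0,B:1.0)97:0.5,C:2.0);"
        back = newick_to_tree(s)
        assert back.root.children[0].support == 97.0

    def test_random_tree_bipartition_preserving_round_trip(self, tmp_path):
        rng = random.Random(20)
        root = random_additive_tree(rng, 20)
        t = PhyloTree(root=root)
        p = tmp_path / "r.nwk"
        write_newick(t, p)
        back = read_newick(p)
        assert back.bipartitions() == t.bipartitions()
        assert sorted(back.leaf_names()) == sorted(t.leaf_names())

    def test_malformed_newick_raises(self):
        with pytest.raises(ValueError):
            newick_to_tree("((A:1,B:2;")


def test_k2p_matrix_symmetric_zero_diagonal(default_clade):
    dm = k2p_matrix(default_clade.alignments["ND2"])
    np.testing.assert_allclose(dm.matrix, dm.matrix.T)
    assert np.all(np.diag(dm.matrix) == 0)
    assert np.all(dm.matrix >= 0)


def test_outgroup_rotation_preserves_bipartitions(default_clade):
    genes = ["ND1", "Cytb"]
    cat = concatenate({g: default_clade.alignments[g] for g in genes}, genes)
    tree = nj_tree(cat)
    before = tree.bipartitions()
    taxon = tree.leaf_names()[0]
    # pick an outgroup that is a direct child of the root, if any
    rooted = None
    for child in tree.root.children:
        if child.is_leaf:
            rooted = root_with_outgroup(tree, child.name)
            break
    if rooted is not None:
        assert rooted.bipartitions() == before
        assert rooted.root.children[0].is_leaf
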