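"""Neighbor-joining, UPGMA, midpoint rooting and ascending ladderization."""

import itertools

import numpy as np
import pytest

from conftest import random_weighted_tree
from mpact.evodist import patristic_matrix
from mpact.seqio import PairMatrix, read_newick
from mpact.treekit import (
    ladderize_ascending,
    leaf_order,
    midpoint_root,
    nj_tree,
    upgma_merge_order,
    upgma_tree,
)
from mpact.viz import to_distance


def dist_matrix(labels, values):
    return PairMatrix(labels, np.asarray(values, float), "ml_distance")


class TestNj:
    def test_four_taxon_additive_recovery(self):
        source = read_newick("((A:1,B:2):1,(C:3,D:4):1);")
        m = patristic_matrix(source)
        tree = nj_tree(m)
        back = patristic_matrix(tree).reorder(m.labels)
        assert np.allclose(back.values, m.values, atol=1e-9)

    def test_three_taxon_formulas(self):
        m = dist_matrix(["A", "B", "C"], [[0, 2, 4], [2, 0, 4], [4, 4, 0]])
        tree = nj_tree(m)
        limbs = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert limbs == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_additivity_roundtrip_quantified(self):
        """patristic(nj(D)) == D to 1e-9 on 100 random additive matrices."""
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            source = random_weighted_tree(n, rng)
            m = patristic_matrix(source)
            back = patristic_matrix(nj_tree(m)).reorder(m.labels)
            assert np.max(np.abs(back.values - m.values)) < 1e-9

    def test_matches_library_nj_on_additive_input(self):
        """Independent oracle: scikit-bio's NJ gives the same patristic
        distances on additive input."""
        import io

        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        source = random_weighted_tree(8, rng)
        m = patristic_matrix(source)
        sk_tree = skbio_nj(DistanceMatrix(m.values, ids=m.labels))
        ours = patristic_matrix(nj_tree(m))
        for a, b in itertools.combinations(m.labels, 2):
            assert ours.value(a, b) == pytest.approx(
                sk_tree.find(a).distance(sk_tree.find(b)), abs=1e-6
            )

    def test_similarity_matrix_rejected(self):
        m = PairMatrix(["a", "b", "c"], np.full((3, 3), 100.0), "identity_pct")
        with pytest.raises(ValueError, match="similarity-oriented"):
            nj_tree(m)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(dist_matrix(["a", "b"], [[0, 1], [1, 0]]))


class TestUpgma:
    def test_two_taxa_half_distance(self):
        tree = upgma_tree(dist_matrix(["A", "B"], [[0, 4], [4, 0]]))
        lengths = [leaf.edge.length for leaf in tree.leaf_node_iter()]
        assert lengths == pytest.approx([2.0, 2.0])

    def test_ultrametric_roundtrip(self):
        # ultrametric distances: UPGMA must reproduce them exactly
        m = dist_matrix(
            ["A", "B", "C", "D"],
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]],
        )
        back = patristic_matrix(upgma_tree(m)).reorder(m.labels)
        assert np.allclose(back.values, m.values, atol=1e-12)

    def test_merge_order_matches_naive_agglomeration(self):
        """Oracle: direct O(n³) average-linkage agglomeration."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = 8
            raw = rng.uniform(1, 10, size=(n, n))
            D = (raw + raw.T) / 2
            np.fill_diagonal(D, 0)
            labels = [f"t{i}" for i in range(n)]
            merges = upgma_merge_order(labels, D)

            # naive oracle with identical tie rule
            clusters = {i: [i] for i in range(n)}
            cur = {i: D.copy() for i in [0]}[0]
            dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
            rep = {i: labels[i] for i in range(n)}
            active = set(range(n))
            nid = n
            expected = []
            while len(active) > 1:
                best = None
                for a, b in itertools.combinations(sorted(active), 2):
                    key = (dist[(min(a, b), max(a, b))], *sorted((rep[a], rep[b])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
                _, a, b = best
                expected.append((a, b))
                for c in active:
                    if c in (a, b):
                        continue
                    na, nb = len(clusters[a]), len(clusters[b])
                    d_new = (
                        na * dist[(min(a, c), max(a, c))]
                        + nb * dist[(min(b, c), max(b, c))]
                    ) / (na + nb)
                    dist[(min(c, nid), max(c, nid))] = d_new
                clusters[nid] = clusters[a] + clusters[b]
                rep[nid] = min(rep[a], rep[b])
                active -= {a, b}
                active.add(nid)
                nid += 1
            assert merges == expected

    def test_leaf_heights_equal_half_merge_distance(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(1, 5, size=(5, 5))
        D = (raw + raw.T) / 2
        np.fill_diagonal(D, 0)
        tree = upgma_tree(dist_matrix([f"t{i}" for i in range(5)], D))
        # ultrametric output: all root-to-leaf path lengths equal
        depths = []
        for leaf in tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        assert np.allclose(depths, depths[0])


class TestMidpointRoot:
    def test_two_leaf_tree(self):
        tree = read_newick("(A:1,B:3);")
        rooted = midpoint_root(tree)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in rooted.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 2.0, "B": 2.0})

    def test_midpoint_on_long_edge(self):
        tree = read_newick("((A:1,B:1):1,C:4);")
        rooted = midpoint_root(tree)
        # longest path A-C of length 6; root 3 from C on the C edge
        c = [x for x in rooted.leaf_node_iter() if x.taxon.label == "C"][0]
        assert c.parent_node is rooted.seed_node
        assert c.edge.length == pytest.approx(3.0)

    def test_max_root_to_leaf_is_half_diameter(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            tree = random_weighted_tree(10, rng)
            m = patristic_matrix(tree)
            diameter = m.values.max()
            rooted = midpoint_root(tree)
            depths = []
            for leaf in rooted.leaf_node_iter():
                d, node = 0.0, leaf
                while node.parent_node is not None:
                    d += node.edge.length or 0.0
                    node = node.parent_node
                depths.append(d)
            assert max(depths) == pytest.approx(diameter / 2.0, abs=1e-9)

    def test_preserves_patristic_distances(self):
        rng = np.random.default_rng(10)
        tree = random_weighted_tree(12, rng)
        before = patristic_matrix(tree)
        after = patristic_matrix(midpoint_root(tree)).reorder(before.labels)
        assert np.allclose(after.values, before.values, atol=1e-9)

    def test_zero_length_tree_warns(self):
        tree = read_newick("((A:0,B:0):0,C:0);")
        with pytest.warns(RuntimeWarning, match="zero"):
            midpoint_root(tree)


class TestLadderize:
    def test_children_sorted_by_subtree_height(self):
        tree = read_newick("((A:3,B:3):1,C:1);", rooted=True)
        lad = ladderize_ascending(tree)
        assert leaf_order(lad) == ["C", "A", "B"]

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        tree = midpoint_root(random_weighted_tree(10, rng))
        once = ladderize_ascending(tree)
        twice = ladderize_ascending(once)
        assert leaf_order(once) == leaf_order(twice)

    def test_matches_naive_recursive_sort(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            tree = midpoint_root(random_weighted_tree(9, rng))
            lad = ladderize_ascending(tree)

            def height(node):
                if node.is_leaf():
                    return 0.0
                return max(height(c) + c.edge.length for c in node.child_nodes())

            def min_label(node):
                return min(l.taxon.label for l in node.leaf_iter())

            def naive(node):
                if node.is_leaf():
                    return [node.taxon.label]
                kids = sorted(
                    node.child_nodes(),
                    key=lambda c: (height(c) + c.edge.length, min_label(c)),
                )
                return [x for k in kids for x in naive(k)]

            assert leaf_order(lad) == naive(tree.seed_node)

    def test_preserves_topology_and_lengths(self):
        rng = np.random.default_rng(13)
        tree = midpoint_root(random_weighted_tree(10, rng))
        before = patristic_matrix(tree)
        after = patristic_matrix(ladderize_ascending(tree)).reorder(before.labels)
        assert np.allclose(after.values, before.values, atol=1e-12)
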