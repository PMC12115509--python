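"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest

from mpact.fixtures import FixtureSpec, simulate_family


# ---------------------------------------------------------------------------
# Independent brute-force alignment oracle
# ---------------------------------------------------------------------------


def brute_force_align_score(a, b, score_fn, gap_open, gap_extend, end_gaps_penalized):
    """Exhaustive enumeration over every global alignment of a and b.

    Scoring convention: a gap run of length L costs open + (L-1)·extend;
    with end gaps unpenalized, runs lying at either end of the alignment
    (before the other sequence starts / after it ends) cost nothing.
    Independent of the DP implementation (pure recursion, no tables).
    """
    n, m = len(a), len(b)
    best = [-np.inf]

    def rec(i, j, last, sc):
        if i == n and j == m:
            if sc > best[0]:
                best[0] = sc
            return
        if i < n and j < m:
            rec(i + 1, j + 1, "M", sc + score_fn(a[i], b[j]))
        if i < n:  # gap in b (consumes a); run position is fixed by j
            free = (not end_gaps_penalized) and (j == 0 or j == m)
            cost = 0.0 if free else (gap_extend if last == "X" else gap_open)
            rec(i + 1, j, "X", sc - cost)
        if j < m:  # gap in a (consumes b)
            free = (not end_gaps_penalized) and (i == 0 or i == n)
            cost = 0.0 if free else (gap_extend if last == "Y" else gap_open)
            rec(i, j + 1, "Y", sc - cost)

    rec(0, 0, None, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# Random weighted trees (for additivity / patristic oracles)
# ---------------------------------------------------------------------------


def random_weighted_tree(n_leaves, rng, min_len=0.1, max_len=1.0):
    """Random bifurcating tree with uniform branch lengths; unrooted shape
    (trifurcating seed) so NJ round-trips are exact."""
    labels = [f"t{i}" for i in range(n_leaves)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in labels]
    for node in nodes:
        node.edge.length = float(rng.uniform(min_len, max_len))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        parent.edge.length = float(rng.uniform(min_len, max_len))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def patristic_by_graph(tree):
    """Independent all-pairs patristic oracle via networkx shortest paths."""
    import networkx as nx

    g = nx.Graph()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            g.add_edge(id(edge.tail_node), id(edge.head_node), weight=edge.length or 0.0)
    leaves = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    labels = sorted(leaves)
    out = {}
    for a, b in itertools.combinations(labels, 2):
        out[(a, b)] = nx.shortest_path_length(g, leaves[a], leaves[b], weight="weight")
    return out


# ---------------------------------------------------------------------------
# Shared simulated family (module-scope: alignment of 12×250aa is not free)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def planted_family():
    spec = FixtureSpec(
        n_groups=3,
        seqs_per_group=4,
        length=250,
        intra_divergence=0.08,
        inter_divergence=2.0,
        alphabet="amino_acid",
        seed=11,
    )
    return simulate_family(spec)


@pytest.fixture(scope="session")
def planted_similarity(planted_family):
    from mpact.pairwise import all_vs_all_sequences

    records, labels, _ = planted_family
    ident, simil = all_vs_all_sequences(records)
    return ident, simil, labels
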