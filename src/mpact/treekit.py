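"""Distance-based tree algorithms shared by clustering and partitioning:
neighbor-joining, UPGMA, midpoint rooting and ascending ladderization.

All functions operate on dendropy trees.  Determinism matters here because
the ladderized leaf order drives data partitioning: every tie (Q-matrix
minima, equal merge distances, equal subtree heights, equal-length leaf
paths) is broken by an explicit rule so repeated runs give identical trees.
"""

from __future__ import annotations

import itertools
import warnings

import dendropy
import numpy as np

from .seqio import PairMatrix, Tree

__all__ = [
    "nj_tree",
    "upgma_tree",
    "upgma_merge_order",
    "midpoint_root",
    "ladderize_ascending",
    "leaf_order",
]


def _require_distance(d: PairMatrix) -> None:
    if d.orientation != "distance":
        raise ValueError(
            f"matrix of metric {d.metric!r} is similarity-oriented; convert with to_distance first"
        )


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------


def nj_tree(d: PairMatrix) -> Tree:
    """Saitou–Nei neighbor-joining; exact on additive matrices.

    Negative branch-length estimates are clamped to 0 with the deficit moved
    to the sibling edge (their sum is preserved).  Ties on the Q-matrix are
    broken by the smallest (i, j) index pair.  Returns an unrooted tree whose
    seed node is the final trifurcation.
    """
    _require_distance(d)
    n = d.n
    if n < 3:
        raise ValueError("neighbor-joining requires at least 3 taxa")

    taxa = dendropy.TaxonNamespace(d.labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in d.labels]
    D = d.values.copy()
    active = list(range(n))  # indices into current D rows
    node_of = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q, ties by smallest (i, j) position pair
        best = np.inf
        bi = bj = -1
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] < best - 1e-12:
                    best, bi, bj = Q[i, j], i, j
        dij = sub[bi, bj]
        limb_i = 0.5 * dij + (r[bi] - r[bj]) / (2.0 * (m - 2))
        limb_j = dij - limb_i
        if limb_i < 0:
            limb_i, limb_j = 0.0, dij
        elif limb_j < 0:
            limb_i, limb_j = dij, 0.0

        parent = dendropy.Node()
        a, b = active[bi], active[bj]
        parent.add_child(node_of[a])
        parent.add_child(node_of[b])
        node_of[a].edge.length = limb_i
        node_of[b].edge.length = limb_j

        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0] + 1)
        for t, k in enumerate(active):
            if k in (a, b):
                continue
            new_row[k] = 0.5 * (D[a, k] + D[b, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        new_idx = D.shape[0] - 1
        D[new_idx, : new_idx] = new_row[:new_idx]
        D[:new_idx, new_idx] = new_row[:new_idx]
        node_of[new_idx] = parent
        active = [k for k in active if k not in (a, b)] + [new_idx]

    # final trifurcation via the three-point formulas
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    root = dendropy.Node()
    limbs = {
        i: 0.5 * (dij + dik - djk),
        j: 0.5 * (dij + djk - dik),
        k: 0.5 * (dik + djk - dij),
    }
    for key in (i, j, k):
        root.add_child(node_of[key])
        node_of[key].edge.length = max(limbs[key], 0.0)

    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def upgma_merge_order(labels: list[str], D: np.ndarray) -> list[tuple[int, int]]:
    """Average-linkage agglomeration order.

    Returns merge pairs of cluster ids (leaves are 0..n-1, internal clusters
    n, n+1, ... in merge order).  Ties on the merge distance are broken by
    the lexicographically smallest pair of cluster representative labels
    (representative = smallest member leaf label).
    """
    n = len(labels)
    dist = {}
    size = {i: 1 for i in range(n)}
    rep = {i: labels[i] for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        dist[(i, j)] = float(D[i, j])
    active = set(range(n))
    merges: list[tuple[int, int]] = []
    next_id = n

    def get(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            key = (get(a, b), *sorted((rep[a], rep[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        merges.append((a, b))
        new = next_id
        next_id += 1
        for c in active:
            if c in (a, b):
                continue
            dnew = (size[a] * get(a, c) + size[b] * get(b, c)) / (size[a] + size[b])
            dist[(min(c, new), max(c, new))] = dnew
        active.discard(a)
        active.discard(b)
        active.add(new)
        size[new] = size[a] + size[b]
        rep[new] = min(rep[a], rep[b])
    return merges


def upgma_tree(d: PairMatrix) -> Tree:
    """Rooted ultrametric average-linkage tree; node heights are half the
    merge distance."""
    _require_distance(d)
    n = d.n
    if n < 2:
        raise ValueError("UPGMA requires at least 2 taxa")
    taxa = dendropy.TaxonNamespace(d.labels)
    node_of = {i: dendropy.Node(taxon=taxa.get_taxon(lab)) for i, lab in enumerate(d.labels)}
    height = {i: 0.0 for i in range(n)}
    size = {i: 1 for i in range(n)}
    # recompute merge distances alongside the shared merge-order routine
    merges = upgma_merge_order(d.labels, d.values)
    dist = {
        (i, j): float(d.values[i, j]) for i, j in itertools.combinations(range(n), 2)
    }

    def get(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    active = set(range(n))
    next_id = n
    root = None
    for a, b in merges:
        h = get(a, b) / 2.0
        parent = dendropy.Node()
        parent.add_child(node_of[a])
        parent.add_child(node_of[b])
        node_of[a].edge.length = max(h - height[a], 0.0)
        node_of[b].edge.length = max(h - height[b], 0.0)
        new = next_id
        next_id += 1
        for c in active:
            if c in (a, b):
                continue
            dist[(min(c, new), max(c, new))] = (
                size[a] * get(a, c) + size[b] * get(b, c)
            ) / (size[a] + size[b])
        active.discard(a)
        active.discard(b)
        active.add(new)
        node_of[new] = parent
        height[new] = h
        size[new] = size[a] + size[b]
        root = parent
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Midpoint rooting
# ---------------------------------------------------------------------------


def _leaf_distances(tree: Tree) -> tuple[list, np.ndarray]:
    leaves = list(tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
    return leaves, D


def _node_path(u, v) -> list:
    """Node path from leaf u to leaf v via their most recent common ancestor."""
    anc_u = [u]
    node = u
    while node.parent_node is not None:
        node = node.parent_node
        anc_u.append(node)
    anc_set = set(id(x) for x in anc_u)
    path_v = [v]
    node = v
    while id(node) not in anc_set:
        node = node.parent_node
        path_v.append(node)
    mrca = node
    path_u = anc_u[: anc_u.index(mrca) + 1]
    return path_u + list(reversed(path_v[:-1]))


def midpoint_root(t: Tree) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    If the midpoint falls exactly on a node, the tree is rooted there;
    otherwise the edge is split by a new root node.  Ties between
    equal-length paths are broken by lexicographic leaf-pair order.  The
    input tree is not modified.
    """
    tree = t.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            edge.length = 0.0
    leaves, D = _leaf_distances(tree)
    if not len(leaves):
        raise ValueError("tree has no leaves")
    diameter = D.max() if D.size else 0.0
    if diameter <= 0.0:
        warnings.warn("all branch lengths are zero; rooting at an arbitrary internal node",
                      RuntimeWarning, stacklevel=2)
        tree.is_rooted = True
        return tree

    # longest path; ties by lexicographic (label_u, label_v)
    best = None
    for i, j in itertools.combinations(range(len(leaves)), 2):
        if abs(D[i, j] - diameter) <= 1e-12:
            pair = sorted((leaves[i].taxon.label, leaves[j].taxon.label))
            cand = (tuple(pair), i, j)
            if best is None or cand < best:
                best = cand
    (lab_u, _), i, j = best[0], best[1], best[2]
    u, v = leaves[i], leaves[j]
    if u.taxon.label != lab_u:
        u, v = v, u

    path = _node_path(u, v)
    half = diameter / 2.0
    acc = 0.0
    for a, b in zip(path, path[1:]):
        # edge between a and b; length stored on whichever is the child
        if b.parent_node is a:
            child, edge_len = b, b.edge.length or 0.0
            towards_child = True
        else:
            child, edge_len = a, a.edge.length or 0.0
            towards_child = False
        if acc + edge_len >= half - 1e-12:
            x = half - acc  # distance from a along this edge
            if abs(x) <= 1e-12:
                target = a
                tree.reroot_at_node(target, update_bipartitions=False)
                break
            if abs(edge_len - x) <= 1e-12:
                tree.reroot_at_node(b, update_bipartitions=False)
                break
            # split the edge x away from a
            parent = child.parent_node
            dist_from_child = (edge_len - x) if towards_child else x
            new = dendropy.Node()
            parent.remove_child(child)
            parent.add_child(new)
            new.edge.length = edge_len - dist_from_child
            new.add_child(child)
            child.edge.length = dist_from_child
            tree.reroot_at_node(new, update_bipartitions=False)
            break
        acc += edge_len
    tree.suppress_unifurcations()
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Ladderization
# ---------------------------------------------------------------------------


def _annotate(node) -> tuple[float, str]:
    """(max root-to-leaf length below node, smallest leaf label below node)"""
    if node.is_leaf():
        node._height = 0.0
        node._min_label = node.taxon.label
        return 0.0, node._min_label
    heights, labels = [], []
    for child in node.child_nodes():
        h, lab = _annotate(child)
        heights.append(h + (child.edge.length or 0.0))
        labels.append(lab)
    node._height = max(heights)
    node._min_label = min(labels)
    return node._height, node._min_label


def ladderize_ascending(t: Tree) -> Tree:
    """Sort every node's children by increasing subtree height, ties by
    smallest leaf label.  Idempotent; topology and branch lengths unchanged.
    The resulting leaf order defines the partition traversal order."""
    tree = t.clone(depth=1)
    _annotate(tree.seed_node)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = list(node.child_nodes())
        children.sort(
            key=lambda c: (c._height + (c.edge.length or 0.0), c._min_label)
        )
        node.set_child_nodes(children)
    return tree


def leaf_order(t: Tree) -> list[str]:
    return [leaf.taxon.label for leaf in t.leaf_node_iter()]
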