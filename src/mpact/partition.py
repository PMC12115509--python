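"""Taxon demarcation: partition a dataset into clusters whose pairwise
metric values all lie within user-defined bounds.

The midpoint-rooted, ascending-ladderized NJ tree of the distance-converted
matrix is the traversal scaffold.  Walking clades root-down, a clade is
emitted as one cluster iff every pairwise value among its leaves satisfies
the bounds and its parent clade does not; leaves covered by no qualifying
clade of size ≥ 2 become singletons.  An alternative ``runs`` mode groups
maximal runs of the ladderized leaf order instead.
"""

from __future__ import annotations

import itertools
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import (
    PairMatrix,
    SequenceRecord,
    Tree,
    read_newick,
    write_fasta,
    write_newick,
)
from .treekit import ladderize_ascending, leaf_order, midpoint_root, nj_tree
from .viz import clustered_heatmap, to_distance

__all__ = [
    "PartitionSet",
    "partition",
    "intra_inter_ranges",
    "write_partition_outputs",
    "read_partition_membership",
]

#: Values are compared to the bounds after rounding to this many decimals,
#: to avoid float-boundary flapping; bounds are inclusive on both ends.
ROUND_DECIMALS = 4


@dataclass
class PartitionSet:
    """Ordered clusters of record ids produced under one metric's bounds."""

    metric: str
    lower: float
    upper: float
    clusters: list[list[str]]
    tree: Tree | None = None
    mode: str = "clades"

    def __post_init__(self) -> None:
        flat = [x for c in self.clusters for x in c]
        if len(set(flat)) != len(flat):
            raise ValueError("clusters are not disjoint")

    @property
    def labels(self) -> list[str]:
        return [x for c in self.clusters for x in c]

    def assignment(self) -> dict[str, int]:
        return {x: i for i, c in enumerate(self.clusters) for x in c}


def _within_bounds(values: np.ndarray, lower: float, upper: float) -> bool:
    v = np.round(values, ROUND_DECIMALS)
    return bool(np.all(v >= lower) and np.all(v <= upper))


def _clade_ok(m: PairMatrix, members: list[str], lower: float, upper: float) -> bool:
    idx = [m.labels.index(x) for x in members]
    sub = m.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return _within_bounds(sub[iu], lower, upper)


def partition(
    m: PairMatrix,
    lower: float,
    upper: float,
    mode: str = "clades",
) -> PartitionSet:
    """Partition the dataset under inclusive bounds in the metric's units.

    ``mode="clades"`` (default) emits maximal qualifying clades of the
    midpoint-rooted ladderized NJ tree; ``mode="runs"`` emits maximal
    qualifying runs of the ladderized leaf order.
    """
    if lower > upper:
        raise ValueError(f"invalid bounds: lower ({lower}) > upper ({upper})")
    if mode not in ("clades", "runs"):
        raise ValueError(f"unknown partition mode {mode!r}")

    if m.n < 3:
        warnings.warn(
            "fewer than 3 records: falling back to threshold-only grouping",
            RuntimeWarning,
            stacklevel=2,
        )
        if m.n == 2 and _clade_ok(m, m.labels, lower, upper):
            clusters = [list(m.labels)]
        else:
            clusters = [[x] for x in m.labels]
        return PartitionSet(m.metric, lower, upper, clusters, None, mode)

    tree = ladderize_ascending(midpoint_root(nj_tree(to_distance(m))))
    order = leaf_order(tree)

    clusters: list[list[str]] = []
    if mode == "clades":
        def walk(node) -> None:
            members = [leaf.taxon.label for leaf in node.leaf_iter()]
            if len(members) >= 2 and _clade_ok(m, members, lower, upper):
                clusters.append(sorted(members, key=order.index))
                return
            if node.is_leaf():
                clusters.append(members)
                return
            for child in node.child_nodes():
                walk(child)

        walk(tree.seed_node)
    else:  # runs mode
        run: list[str] = []
        for lab in order:
            if run and not _clade_ok(m, run + [lab], lower, upper):
                clusters.append(run)
                run = []
            run.append(lab)
        if run:
            clusters.append(run)

    clusters.sort(key=lambda c: order.index(c[0]))
    result = PartitionSet(m.metric, lower, upper, clusters, tree, mode)

    # post-hoc self-check of the within-cluster bound invariant
    for c in result.clusters:
        if len(c) >= 2:
            assert _clade_ok(m, c, lower, upper), "within-cluster bound violated"
    assert sorted(result.labels) == sorted(m.labels), "not a partition"
    return result


# ---------------------------------------------------------------------------
# Intra/intergroup value ranges
# ---------------------------------------------------------------------------


def intra_inter_ranges(m: PairMatrix, group_labels: dict[str, object]) -> pd.DataFrame:
    """Per-group intragroup and intergroup value ranges.

    ``group_labels`` maps every matrix label to a group key.  Intragroup
    pairs are unordered pairs within the group; intergroup pairs go from the
    group to all non-members.  The returned frame carries the dataset-wide
    off-diagonal mean and sd in ``df.attrs['mean']`` / ``df.attrs['sd']``.
    """
    missing = [x for x in m.labels if x not in group_labels]
    if missing:
        raise ValueError(f"labels without group assignment: {', '.join(missing)}")
    groups: dict[object, list[int]] = {}
    for i, lab in enumerate(m.labels):
        groups.setdefault(group_labels[lab], []).append(i)

    rows = []
    for gname in groups:
        idx = groups[gname]
        other = [i for i in range(m.n) if i not in idx]
        intra = (
            np.array([m.values[i, j] for i, j in itertools.combinations(idx, 2)])
            if len(idx) >= 2
            else np.array([])
        )
        inter = m.values[np.ix_(idx, other)].ravel() if other else np.array([])
        rows.append(
            {
                "group": gname,
                "n_members": len(idx),
                "intra_min": intra.min() if intra.size else np.nan,
                "intra_max": intra.max() if intra.size else np.nan,
                "inter_min": inter.min() if inter.size else np.nan,
                "inter_max": inter.max() if inter.size else np.nan,
                "flag": "" if intra.size else "single-member",
            }
        )
    df = pd.DataFrame(rows).set_index("group")
    off = m.offdiagonal()
    df.attrs["mean"] = float(off.mean())
    df.attrs["sd"] = float(off.std(ddof=1)) if off.size > 1 else 0.0
    return df


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------


def write_partition_outputs(
    p: PartitionSet,
    records: list[SequenceRecord],
    out_dir: str,
    matrix: PairMatrix | None = None,
) -> dict:
    """Write one FASTA per cluster, the rooted NJ tree (Newick), a
    cluster-membership TSV, and (if the metric matrix is given) a heatmap
    with cluster boundaries drawn.  Returns produced file paths."""
    by_id = {r.id: r for r in records}
    missing = [x for x in p.labels if x not in by_id]
    if missing:
        raise ValueError(f"records missing for labels: {', '.join(missing)}")
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, object] = {"fasta": []}

    for k, cluster in enumerate(p.clusters, start=1):
        path = os.path.join(out_dir, f"cluster_{k:03d}.fasta")
        write_fasta([by_id[x] for x in cluster], path)
        paths["fasta"].append(path)

    tsv = os.path.join(out_dir, "membership.tsv")
    with open(tsv, "w") as fh:
        fh.write(f"#metric={p.metric}\tlower={p.lower}\tupper={p.upper}\tmode={p.mode}\n")
        fh.write("record\tcluster\n")
        for k, cluster in enumerate(p.clusters, start=1):
            for x in cluster:
                fh.write(f"{x}\t{k}\n")
    paths["membership"] = tsv

    if p.tree is not None:
        nwk = os.path.join(out_dir, "partition_tree.nwk")
        annotated = p.tree.clone(depth=1)
        assign = p.assignment()
        for leaf in annotated.leaf_node_iter():
            leaf.annotations.add_new("cluster", assign[leaf.taxon.label] + 1)
        write_newick(annotated, nwk)
        paths["tree"] = nwk

    if matrix is not None:
        display = [x for c in p.clusters for x in c]
        mm = matrix.reorder(display)
        bounds_idx = np.cumsum([len(c) for c in p.clusters])[:-1]
        info = clustered_heatmap(
            mm,
            os.path.join(out_dir, "partition"),
            tree=None if p.tree is None else _order_tree(p.tree, display),
            boundaries=list(bounds_idx),
        )
        paths["heatmap"] = info["paths"]
    return paths


def _order_tree(tree: Tree, display: list[str]) -> Tree:
    """The partition tree already induces the display order (clusters are
    contiguous in the ladderized leaf order), so reuse it for drawing."""
    return tree


def read_partition_membership(path, tree_path=None) -> PartitionSet:
    """Rebuild a PartitionSet from a membership TSV written by
    :func:`write_partition_outputs`."""
    metric, lower, upper, mode = "identity_pct", 0.0, 0.0, "clades"
    clusters: dict[int, list[str]] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln.startswith("#"):
                for part in ln.lstrip("#").split("\t"):
                    key, _, val = part.partition("=")
                    if key == "metric":
                        metric = val
                    elif key == "lower":
                        lower = float(val)
                    elif key == "upper":
                        upper = float(val)
                    elif key == "mode":
                        mode = val
            elif ln and not ln.startswith("record\t"):
                rec, k = ln.split("\t")
                clusters.setdefault(int(k), []).append(rec)
    tree = read_newick(tree_path, rooted=True) if tree_path else None
    ordered = [clusters[k] for k in sorted(clusters)]
    return PartitionSet(metric, lower, upper, ordered, tree, mode)
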