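"""Clustered heatmaps, frequency-distribution plots and dendrogram export.

Display clustering uses average linkage (UPGMA) on the distance-converted
matrix, matching the tree drawn above the heatmap; the leaf order shown is
exactly the ladderized UPGMA leaf order (asserted in tests, not eyeballed).
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .seqio import METRICS, PairMatrix, Tree, newick_string, write_newick
from .treekit import ladderize_ascending, leaf_order, upgma_tree

__all__ = [
    "to_distance",
    "clustered_heatmap",
    "frequency_plot",
    "FrequencyTable",
    "DEFAULT_BIN_WIDTH",
    "COLOR_ANCHORS",
]

#: Default frequency-plot bin widths per metric (metric units).
DEFAULT_BIN_WIDTH = {
    "identity_pct": 5.0,
    "similarity_pct": 5.0,
    "threedi_similarity_pct": 5.0,
    "tm_score": 0.05,
    "ml_distance": 0.25,
}

#: Heatmap color-scale anchors (vmin, vmax, colormap); warm = similar.
#: ml_distance vmax of None means "span the data".
COLOR_ANCHORS = {
    "identity_pct": (0.0, 100.0, "inferno"),
    "similarity_pct": (0.0, 100.0, "inferno"),
    "threedi_similarity_pct": (0.0, 100.0, "inferno"),
    "tm_score": (0.0, 1.0, "inferno"),
    "ml_distance": (0.0, None, "inferno_r"),
}


def to_distance(m: PairMatrix) -> PairMatrix:
    """Convert any metric matrix to a distance-oriented matrix.

    identity/similarity/3Di: d = (100 − v)/100; tm_score: d = 1 − v;
    ml_distance: unchanged.  Diagonal becomes 0.
    """
    if m.orientation == "distance":
        return m
    if m.metric == "tm_score":
        values = 1.0 - m.values
    else:
        values = (100.0 - m.values) / 100.0
    return PairMatrix(m.labels, values, m.metric, orientation="distance")


# ---------------------------------------------------------------------------
# Clustered heatmap
# ---------------------------------------------------------------------------


def _draw_dendrogram(ax, tree: Tree, order: list[str]) -> None:
    """Draw a rooted tree above the heatmap: leaves at x = column centers."""
    x_of = {lab: i + 0.5 for i, lab in enumerate(order)}
    pos: dict[int, tuple[float, float]] = {}

    def depth(node, acc):
        for child in node.child_nodes():
            depth(child, acc + (child.edge.length or 0.0))
        if node.is_leaf():
            node._depth = acc
        else:
            node._depth = acc

    depth(tree.seed_node, 0.0)
    max_depth = max(leaf._depth for leaf in tree.leaf_node_iter())

    def layout(node):
        if node.is_leaf():
            x = x_of[node.taxon.label]
            y = 0.0  # draw all leaves at the baseline
            pos[id(node)] = (x, y)
            return x
        xs = [layout(c) for c in node.child_nodes()]
        x = (min(xs) + max(xs)) / 2.0
        y = max_depth - node._depth
        pos[id(node)] = (x, y)
        for c in node.child_nodes():
            cx, _ = pos[id(c)]
            cy = 0.0 if c.is_leaf() else max_depth - c._depth
            ax.plot([cx, cx], [cy, y], color="0.25", lw=0.8)
        ax.plot([min(xs), max(xs)], [y, y], color="0.25", lw=0.8)
        return x

    layout(tree.seed_node)
    ax.set_xlim(0, len(order))
    ax.set_ylim(0, max(max_depth, 1e-9) * 1.05)
    ax.axis("off")


def clustered_heatmap(
    m: PairMatrix,
    out_prefix: str,
    tree: Tree | None = None,
    boundaries: list[int] | None = None,
) -> dict:
    """Heatmap of the matrix ordered by the ladderized UPGMA tree of its
    distance conversion, with the dendrogram drawn above.

    Writes ``<prefix>_heatmap.jpg`` / ``.svg``, the leaf order
    (``<prefix>_order.txt``) and the dendrogram (``<prefix>_dendrogram.nwk``).
    ``boundaries`` (row indices in display order) draws cluster separators.
    Returns a dict with the leaf order, tree and file paths.
    """
    if m.n < 2:
        raise ValueError("heatmap requires at least 2 records")
    if tree is None:
        tree = ladderize_ascending(upgma_tree(to_distance(m)))
    order = leaf_order(tree)
    mm = m.reorder(order)

    vmin, vmax, cmap = COLOR_ANCHORS[m.metric]
    if vmax is None:
        vmax = max(float(np.max(mm.values)), 1e-9)

    fig = plt.figure(figsize=(8.5, 9.5))
    gs = fig.add_gridspec(2, 2, height_ratios=[1, 5], width_ratios=[20, 1], hspace=0.02, wspace=0.05)
    ax_tree = fig.add_subplot(gs[0, 0])
    ax_heat = fig.add_subplot(gs[1, 0])
    ax_cbar = fig.add_subplot(gs[1, 1])

    _draw_dendrogram(ax_tree, tree, order)
    im = ax_heat.imshow(
        mm.values,
        cmap=cmap,
        vmin=vmin,
        vmax=vmax,
        aspect="auto",
        extent=(0, mm.n, mm.n, 0),
        interpolation="nearest",
    )
    ticks = np.arange(mm.n) + 0.5
    fontsize = max(2, min(8, 300 // mm.n))
    ax_heat.set_xticks(ticks)
    ax_heat.set_xticklabels(order, rotation=90, fontsize=fontsize)
    ax_heat.set_yticks(ticks)
    ax_heat.set_yticklabels(order, fontsize=fontsize)
    if boundaries:
        for b in boundaries:
            ax_heat.axhline(b, color="white", lw=1.2)
            ax_heat.axvline(b, color="white", lw=1.2)
    fig.colorbar(im, cax=ax_cbar, label=m.metric)
    ax_tree.set_title(f"{m.metric} (n={m.n})", fontsize=10)

    paths = {
        "jpg": f"{out_prefix}_heatmap.jpg",
        "svg": f"{out_prefix}_heatmap.svg",
        "order": f"{out_prefix}_order.txt",
        "newick": f"{out_prefix}_dendrogram.nwk",
    }
    fig.savefig(paths["jpg"], dpi=150)
    fig.savefig(paths["svg"])
    plt.close(fig)
    with open(paths["order"], "w") as fh:
        fh.write("\n".join(order) + "\n")
    write_newick(tree, paths["newick"])
    return {"order": order, "tree": tree, "newick": newick_string(tree), "paths": paths}


# ---------------------------------------------------------------------------
# Frequency distributions
# ---------------------------------------------------------------------------


@dataclass
class FrequencyTable:
    """Binned counts of off-diagonal unordered pair values (each counted
    once).  Bins are contiguous, left-closed/right-open, last bin closed."""

    metric: str
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#metric={self.metric}\n")
            fh.write("bin_start\tbin_end\tcount\n")
            for lo, hi, c in zip(self.bin_edges[:-1], self.bin_edges[1:], self.counts):
                fh.write(f"{lo:.4f}\t{hi:.4f}\t{int(c)}\n")


def frequency_plot(
    m: PairMatrix,
    bin_width: float | None = None,
    out_prefix: str | None = None,
) -> FrequencyTable:
    """Bin the upper-triangle values and (optionally) draw a line plot of
    count vs bin midpoint to ``<prefix>_freq.jpg`` / ``.svg`` and write the
    table to ``<prefix>_freq.tsv``."""
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTH[m.metric]
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = m.offdiagonal()
    spec_range = METRICS[m.metric]["range"]
    lo = 0.0
    hi = spec_range[1] if np.isfinite(spec_range[1]) else float(np.max(values, initial=0.0))
    if m.orientation == "distance" and m.metric != "ml_distance":
        hi = 1.0
    n_bins = max(int(np.ceil((hi - lo) / bin_width - 1e-9)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] < hi - 1e-12:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, _ = np.histogram(values, bins=edges)
    table = FrequencyTable(m.metric, edges, counts)

    if out_prefix is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(table.midpoints, counts, marker="o", ms=3)
        ax.set_xlabel(m.metric)
        ax.set_ylabel("pair count")
        ax.set_title(f"{m.metric} frequency distribution")
        fig.tight_layout()
        fig.savefig(f"{out_prefix}_freq.jpg", dpi=150)
        fig.savefig(f"{out_prefix}_freq.svg")
        plt.close(fig)
        table.to_tsv(f"{out_prefix}_freq.tsv")
    return table
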