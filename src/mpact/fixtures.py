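"""Synthetic data generators with planted structure.

``simulate_family`` evolves sequence families with known group membership
(so planted-partition recovery can be scored), and ``simulate_structures``
builds ideal α-helical Cα traces with known residue correspondences.  All
randomness is driven by a single integer seed; identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .evodist import EvoModel
from .seqio import SequenceRecord, StructureChain, Tree

__all__ = ["FixtureSpec", "simulate_family", "simulate_structures"]


@dataclass
class FixtureSpec:
    """Parameters of a planted sequence family.

    ``intra_divergence`` / ``inter_divergence`` are expected substitutions
    per site between members of one group and between group ancestors,
    respectively.  Group ancestors sit on a random bifurcating tree scaled so
    the *closest* ancestor pair is ``inter_divergence`` apart, guaranteeing
    at least that much separation between any two groups.
    """

    n_groups: int = 3
    seqs_per_group: int = 4
    length: int = 300
    intra_divergence: float = 0.1
    inter_divergence: float = 1.0
    alphabet: str = "amino_acid"
    seed: int = 0
    model: str = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.intra_divergence < self.inter_divergence):
            raise ValueError("require 0 <= intra_divergence < inter_divergence")
        if self.alphabet not in ("nucleotide", "amino_acid"):
            raise ValueError("alphabet must be nucleotide or amino_acid")
        self.model = "JC69" if self.alphabet == "nucleotide" else "Poisson"


def _evolve(seq_idx: np.ndarray, t: float, model: EvoModel, rng: np.random.Generator) -> np.ndarray:
    """Evolve a state-index sequence for time t under the model."""
    if t == 0:
        return seq_idx.copy()
    P = model.transition_probs(t)
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(seq_idx))
    return np.array([np.searchsorted(cum[s], x) for s, x in zip(seq_idx, u)], dtype=np.int64)


def _random_topology(labels: list[str], rng: np.random.Generator) -> dendropy.Tree:
    """Random bifurcating topology by successive random joins, with
    exponential(1) branch lengths."""
    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in labels]
    for node in nodes:
        node.edge.length = float(rng.exponential(1.0))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        parent.edge.length = float(rng.exponential(1.0))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def simulate_family(spec: FixtureSpec) -> tuple[list[SequenceRecord], dict[str, int], Tree]:
    """Simulate a planted sequence family.

    Returns ``(records, true_labels, true_tree)`` where ``true_labels`` maps
    record id → group index and ``true_tree`` is the generating tree
    (ancestor topology with member tips attached).  There is no indel
    process, so the true alignment column map is the identity.
    """
    rng = np.random.default_rng(spec.seed)
    model = EvoModel(spec.model)
    k = len(model.states)
    root_seq = rng.integers(0, k, size=spec.length)

    group_names = [f"g{g + 1}" for g in range(spec.n_groups)]
    if spec.n_groups == 1:
        anc_tree = None
        anc_depth = {group_names[0]: 0.0}
    else:
        anc_tree = _random_topology(group_names, rng)
        # scale so the closest ancestor pair is inter_divergence apart
        pdm = anc_tree.phylogenetic_distance_matrix()
        taxa = list(anc_tree.taxon_namespace)
        dmin = min(
            pdm.patristic_distance(taxa[i], taxa[j])
            for i in range(len(taxa))
            for j in range(i + 1, len(taxa))
        )
        scale = spec.inter_divergence / dmin
        for edge in anc_tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale

    # evolve ancestors down the scaled tree
    anc_seqs: dict[str, np.ndarray] = {}
    if anc_tree is None:
        anc_seqs[group_names[0]] = _evolve(root_seq, spec.intra_divergence / 2.0, model, rng)
    else:
        seq_at = {id(anc_tree.seed_node): root_seq}
        for node in anc_tree.preorder_node_iter():
            if node is anc_tree.seed_node:
                continue
            parent_seq = seq_at[id(node.parent_node)]
            seq_at[id(node)] = _evolve(parent_seq, node.edge.length, model, rng)
            if node.is_leaf():
                anc_seqs[node.taxon.label] = seq_at[id(node)]

    records: list[SequenceRecord] = []
    true_labels: dict[str, int] = {}
    member_branch = spec.intra_divergence / 2.0
    states = model.states
    for g, gname in enumerate(group_names):
        for s in range(spec.seqs_per_group):
            seq = _evolve(anc_seqs[gname], member_branch, model, rng)
            rid = f"{gname}_s{s + 1}"
            records.append(
                SequenceRecord(rid, spec.alphabet, "".join(states[x] for x in seq))
            )
            true_labels[rid] = g

    # generating tree with member tips attached to each ancestor
    all_ids = [r.id for r in records]
    taxa = dendropy.TaxonNamespace(all_ids)
    if anc_tree is None:
        root = dendropy.Node()
        attach = {group_names[0]: root}
        true_tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    else:
        true_tree = dendropy.Tree(taxon_namespace=taxa)
        clone = anc_tree.clone(depth=1)
        true_tree.seed_node = clone.seed_node
        attach = {}
        for leaf in list(true_tree.leaf_node_iter()):
            attach[leaf.taxon.label] = leaf
            leaf.taxon = None
    for rid in all_ids:
        gname = rid.split("_")[0]
        tip = dendropy.Node(taxon=taxa.get_taxon(rid))
        tip.edge.length = member_branch
        attach[gname].add_child(tip)
    true_tree.is_rooted = True
    return records, true_labels, true_tree


def simulate_structures(
    n: int,
    length: int,
    noise_A: float,
    seed: int = 0,
    n_delete: int = 0,
) -> tuple[list[StructureChain], dict[str, dict[int, int]]]:
    """Ideal α-helix Cα traces (rise 1.5 Å, radius 2.3 Å, 100°/residue)
    perturbed by isotropic Gaussian noise of sd ``noise_A``.

    With ``n_delete > 0``, up to that many residues are trimmed from a random
    terminus of each chain after the first.  Returns ``(chains, true_pairs)``
    where ``true_pairs[chain_id]`` maps residue index of that chain to the
    corresponding residue index of chain 0.
    """
    if length < 10:
        raise ValueError("length must be >= 10")
    rng = np.random.default_rng(seed)
    i = np.arange(length)
    theta = np.deg2rad(100.0) * i
    ideal = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])

    chains: list[StructureChain] = []
    true_pairs: dict[str, dict[int, int]] = {}
    for c in range(n):
        coords = ideal + rng.normal(0.0, noise_A, size=ideal.shape)
        start, stop = 0, length
        if c > 0 and n_delete > 0:
            k = int(rng.integers(0, n_delete + 1))
            if rng.random() < 0.5:
                start = k
            else:
                stop = length - k
        cid = f"chain{c + 1}"
        chains.append(StructureChain(cid, coords[start:stop]))
        true_pairs[cid] = {local: start + local for local in range(stop - start)}
    return chains, true_pairs
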