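"""Maximum-likelihood evolutionary distances.

Two pathways produce the ML distance matrix:

* **pairwise mode** — for each pair of MSA rows, the evolutionary time ``t``
  (expected substitutions/site) maximizing the log-likelihood of the observed
  site patterns under a reversible substitution model (JC69 / K80 for
  nucleotides, Poisson / WAG-frequency equal-input for proteins);
* **patristic mode** — path-length distances read off an externally inferred
  tree with branch lengths, which is how a tree-based phylogenetic pipeline
  defines pairwise ML distance.

A minimal progressive aligner (UPGMA guide tree on k-mer distances,
profile–profile affine NW) is included so the pipeline can run
self-contained when no external MSA is supplied.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .pairwise import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    NEG,
    SubstitutionMatrix,
    default_matrix,
    nw_align,
)
from .seqio import GAP, PairMatrix, SequenceRecord, Tree

__all__ = [
    "EvoModel",
    "pairwise_ml_distance",
    "ml_distance_matrix",
    "patristic_matrix",
    "progressive_msa",
    "T_MAX",
]

T_MAX = 10.0  # saturation cap, substitutions/site
_XTOL = 1e-6

NT_STATES = "ACGT"
AA_STATES = "ARNDCQEGHILKMFPSTWYV"

# WAG amino-acid stationary frequencies (order = AA_STATES).
WAG_FREQS = np.array(
    [
        0.0866279, 0.0439720, 0.0390894, 0.0570451, 0.0193078,
        0.0367281, 0.0580589, 0.0832518, 0.0244313, 0.0484660,
        0.0862090, 0.0620286, 0.0195027, 0.0384319, 0.0457631,
        0.0695179, 0.0610127, 0.0143859, 0.0352742, 0.0708956,
    ]
)
WAG_FREQS = WAG_FREQS / WAG_FREQS.sum()


@dataclass
class EvoModel:
    """A reversible substitution model with rate matrix Q normalized to mean
    rate 1, so that ``t`` is in expected substitutions per site.

    ``name`` is one of JC69, K80 (nucleotide), Poisson, WAG_F (amino acid);
    K80 takes a transition/transversion ratio ``kappa``.
    """

    name: str
    kappa: float = 2.0
    states: str = field(init=False)
    freqs: np.ndarray = field(init=False)
    _eig: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        name = self.name.upper().replace("-", "_")
        if name in ("JC69", "JC"):
            name = "JC69"
            self.states = NT_STATES
            self.freqs = np.full(4, 0.25)
            Q = np.full((4, 4), 1.0 / 3.0)
        elif name == "K80":
            name = "K80"
            if self.kappa <= 0:
                raise ValueError("K80 kappa must be positive")
            self.states = NT_STATES
            self.freqs = np.full(4, 0.25)
            beta = 1.0 / (self.kappa + 2.0)
            alpha = self.kappa * beta
            Q = np.full((4, 4), beta)
            transitions = [("A", "G"), ("C", "T")]
            idx = {c: i for i, c in enumerate(self.states)}
            for a, b in transitions:
                Q[idx[a], idx[b]] = Q[idx[b], idx[a]] = alpha
        elif name == "POISSON":
            name = "Poisson"
            self.states = AA_STATES
            self.freqs = np.full(20, 0.05)
            Q = np.full((20, 20), 1.0 / 19.0)
        elif name in ("WAG_F", "WAG_FREQUENCIES", "WAGF"):
            # equal-input (F81-style) model with WAG stationary frequencies
            name = "WAG_F"
            self.states = AA_STATES
            self.freqs = WAG_FREQS.copy()
            beta = 1.0 / (1.0 - np.sum(self.freqs**2))
            Q = beta * np.tile(self.freqs, (20, 1))
        else:
            raise ValueError(f"unknown model {self.name!r}")
        self.name = name
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # reversible Q: eigendecompose the symmetrized generator once
        d = np.sqrt(self.freqs)
        Sym = (Q * d[:, None]) / d[None, :]
        w, V = np.linalg.eigh((Sym + Sym.T) / 2.0)
        self._eig = (w, V, d)

    @property
    def alphabet(self) -> str:
        return "nucleotide" if len(self.states) == 4 else "amino_acid"

    def transition_probs(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); stochastic for t ≥ 0."""
        if t < 0:
            raise ValueError("t must be non-negative")
        w, V, d = self._eig
        P = (V * np.exp(w * t)) @ V.T
        P = P / d[:, None] * d[None, :]
        return np.clip(P, 0.0, None)


def _make_model(model: "EvoModel | str") -> EvoModel:
    return model if isinstance(model, EvoModel) else EvoModel(model)


# ---------------------------------------------------------------------------
# Pairwise ML distances
# ---------------------------------------------------------------------------


def _pair_counts(row_i: str, row_j: str, model: EvoModel) -> np.ndarray:
    """k×k counts of usable site patterns; columns with a gap or ambiguity
    character in either row are excluded pairwise."""
    idx = {c: i for i, c in enumerate(model.states)}
    k = len(model.states)
    counts = np.zeros((k, k))
    for a, b in zip(row_i.upper(), row_j.upper()):
        ia = idx.get(a)
        ib = idx.get(b)
        if ia is not None and ib is not None:
            counts[ia, ib] += 1
    return counts


def pairwise_ml_distance(
    row_i: str | SequenceRecord,
    row_j: str | SequenceRecord,
    model: "EvoModel | str" = "JC69",
    pair_name: str = "",
) -> float:
    """ML evolutionary distance between two aligned rows (substitutions/site).

    Maximizes ``Σ_columns log P(a→b | t)`` by bounded scalar optimization on
    [0, 10] to 1e-6; saturated pairs are capped at t=10 with a warning.
    """
    model = _make_model(model)
    a = row_i.residues if isinstance(row_i, SequenceRecord) else row_i
    b = row_j.residues if isinstance(row_j, SequenceRecord) else row_j
    if len(a) != len(b):
        raise ValueError(f"rows have unequal length ({len(a)} vs {len(b)}){pair_name}")
    counts = _pair_counts(a, b, model)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"zero usable (gap/ambiguity-free) columns for pair{pair_name or ''}")
    if counts.trace() == total:
        return 0.0

    def neg_loglik(t: float) -> float:
        P = model.transition_probs(t)
        with np.errstate(divide="ignore"):
            logP = np.log(P)
        logP[counts == 0] = 0.0  # avoid -inf * 0
        ll = float(np.sum(counts * logP))
        return -ll if np.isfinite(ll) else 1e300

    res = minimize_scalar(neg_loglik, bounds=(0.0, T_MAX), method="bounded", options={"xatol": _XTOL})
    t_hat = float(res.x)
    if t_hat >= T_MAX - 1e-3 or neg_loglik(T_MAX) <= res.fun:
        warnings.warn(
            f"saturated pair{pair_name}: ML distance capped at t_max={T_MAX}",
            RuntimeWarning,
            stacklevel=2,
        )
        return T_MAX
    return max(t_hat, 0.0)


def ml_distance_matrix(msa: list[SequenceRecord], model: "EvoModel | str" = None) -> PairMatrix:
    """Symmetric zero-diagonal matrix of pairwise ML distances over an MSA."""
    if len(msa) < 2:
        raise ValueError("MSA must have at least 2 rows")
    if model is None:
        model = "JC69" if msa[0].alphabet == "nucleotide" else "Poisson"
    model = _make_model(model)
    n = len(msa)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pairwise_ml_distance(msa[i], msa[j], model, pair_name=f" ({msa[i].id}, {msa[j].id})")
        values[i, j] = values[j, i] = d
    return PairMatrix([r.id for r in msa], values, "ml_distance")


# ---------------------------------------------------------------------------
# Patristic distances from an external tree
# ---------------------------------------------------------------------------


def patristic_matrix(tree: Tree) -> PairMatrix:
    """Entry (i, j) = sum of branch lengths on the i→j leaf path."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "internal node"
            raise ValueError(f"missing branch length on edge to {name}")
    pdm = tree.phylogenetic_distance_matrix()
    leaves = [leaf.taxon for leaf in tree.leaf_node_iter()]
    labels = [t.label for t in leaves]
    n = len(labels)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(leaves[i], leaves[j])
        values[i, j] = values[j, i] = d
    return PairMatrix(labels, values, "ml_distance")


# ---------------------------------------------------------------------------
# Minimal progressive MSA (self-contained pipeline mode)
# ---------------------------------------------------------------------------


def _kmer_distance(a: str, b: str, k: int) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    shared = len(ka & kb)
    return 1.0 - shared / min(len(ka), len(kb))


def _profile_from(rows: list[str], m: SubstitutionMatrix) -> np.ndarray:
    """L×(k+1) column frequency profile; last slot is the gap fraction."""
    k = len(m.letters)
    L = len(rows[0])
    prof = np.zeros((L, k + 1))
    idx = m._index
    for row in rows:
        for pos, c in enumerate(row):
            if c == GAP:
                prof[pos, k] += 1
            else:
                prof[pos, idx[c]] += 1
    return prof / len(rows)


def _profile_align(
    rows_a: list[str],
    rows_b: list[str],
    m: SubstitutionMatrix,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Affine NW on profile columns; score = expected substitution score."""
    pa = _profile_from(rows_a, m)
    pb = _profile_from(rows_b, m)
    k = len(m.letters)
    S = pa[:, :k] @ m.scores @ pb[:, :k].T
    from .pairwise import _gotoh_kernel

    # end gaps ARE penalized here: with free ends, dissimilar profiles would
    # collapse to fully staggered (all-gap) merges
    _, pM, pX, pY, state = _gotoh_kernel(S, float(gap_open), float(gap_extend), False)
    i, j = S.shape
    ops = []
    while i > 0 or j > 0:
        if state == 0:
            ops.append("M")
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops.append("X")
            state = pX[i, j]
            i -= 1
        else:
            ops.append("Y")
            state = pY[i, j]
            j -= 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "X"):
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += GAP
        if op in ("M", "Y"):
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ib += 1
        else:
            for r in range(len(rows_b)):
                out_b[r] += GAP
    return out_a, out_b


def progressive_msa(
    records: list[SequenceRecord],
    m: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[SequenceRecord]:
    """Progressive multiple alignment along a UPGMA guide tree built from
    k-mer distances (k = 3 for proteins/3Di, 6 for nucleotides).

    Deterministic given input order.  Intended for self-contained runs; an
    externally computed MSA should be preferred when available.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    if m is None:
        m = default_matrix(records[0].alphabet)
    if len(records) == 2:
        r = nw_align(records[0], records[1], m, gap_open, gap_extend)
        aligned = [r.aligned_a, r.aligned_b]
        return [
            SequenceRecord(rec.id, rec.alphabet, row, rec.description, aligned=True)
            for rec, row in zip(records, aligned)
        ]

    k = 6 if records[0].alphabet == "nucleotide" else 3
    n = len(records)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = _kmer_distance(records[i].residues, records[j].residues, k)

    from .treekit import upgma_merge_order

    merges = upgma_merge_order([r.id for r in records], D)
    # each cluster holds (member indices, aligned rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].residues]) for i in range(n)
    }
    next_id = n
    for left, right in merges:
        ia, rows_a = clusters.pop(left)
        ib, rows_b = clusters.pop(right)
        out_a, out_b = _profile_align(rows_a, rows_b, m, gap_open, gap_extend)
        clusters[next_id] = (ia + ib, out_a + out_b)
        next_id += 1
    (members, rows), = clusters.values()
    order = np.argsort(members)
    return [
        SequenceRecord(
            records[members[o]].id,
            records[members[o]].alphabet,
            rows[o],
            records[members[o]].description,
            aligned=True,
        )
        for o in order
    ]
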