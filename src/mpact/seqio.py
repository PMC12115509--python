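"""Readers and writers for every external format the toolbox touches.

Sequence data (FASTA, three alphabets), protein structures (PDB, Cα trace),
trees (Newick) and pairwise metric matrices (TSV) all enter and leave the
program through this module.  All readers are strict: malformed input is
rejected with a diagnostic, never silently repaired.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

__all__ = [
    "ALPHABETS",
    "METRICS",
    "SequenceRecord",
    "StructureChain",
    "PairMatrix",
    "Tree",
    "read_fasta",
    "write_fasta",
    "read_msa",
    "write_msa",
    "read_pdb_ca",
    "read_matrix",
    "write_matrix",
    "read_newick",
    "write_newick",
]

# ---------------------------------------------------------------------------
# Alphabets and metric registry
# ---------------------------------------------------------------------------

#: Valid residue characters per declared alphabet.  Nucleotide includes the
#: IUPAC ambiguity codes, amino acid the 20 standard residues plus
#: B/Z/X/J/U/O and the stop character '*'.  The 3Di structural alphabet uses
#: the same 20 letters as the amino-acid alphabet.
ALPHABETS: dict[str, frozenset[str]] = {
    "nucleotide": frozenset("ACGTUNRYSWKMBDHV"),
    "amino_acid": frozenset("ACDEFGHIKLMNPQRSTVWY" "BZXJUO*"),
    "threedi": frozenset("ACDEFGHIKLMNPQRSTVWY"),
}

GAP = "-"

#: Metric registry: orientation and the required diagonal value.
METRICS: dict[str, dict] = {
    "identity_pct": {"orientation": "similarity", "diag": 100.0, "range": (0.0, 100.0)},
    "similarity_pct": {"orientation": "similarity", "diag": 100.0, "range": (0.0, 100.0)},
    "threedi_similarity_pct": {"orientation": "similarity", "diag": 100.0, "range": (0.0, 100.0)},
    "tm_score": {"orientation": "similarity", "diag": 1.0, "range": (0.0, 1.0)},
    "ml_distance": {"orientation": "distance", "diag": 0.0, "range": (0.0, math.inf)},
}

#: Permissive-mode replacement characters per alphabet.
_PERMISSIVE_SUB = {"nucleotide": "N", "amino_acid": "X", "threedi": "D"}

#: Type alias: trees are dendropy trees throughout the package.
Tree = dendropy.Tree


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """A named sequence over a declared alphabet.

    ``id`` must contain no whitespace; ``residues`` is stored uppercase and
    validated against the alphabet at construction (``'-'`` additionally
    allowed when ``aligned=True``).
    """

    id: str
    alphabet: str
    residues: str
    description: str = ""
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id {self.id!r}: empty or contains whitespace")
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        valid = ALPHABETS[self.alphabet] | ({GAP} if self.aligned else set())
        for pos, c in enumerate(self.residues):
            if c not in valid:
                raise ValueError(
                    f"record {self.id!r}: invalid character {c!r} for alphabet "
                    f"{self.alphabet!r} at position {pos + 1}"
                )

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureChain:
    """Ordered Cα trace of one protein chain (coordinates in Å)."""

    id: str
    ca_coords: np.ndarray  # (L, 3) float
    residue_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError(f"chain {self.id!r}: coordinates must be (L, 3)")
        if len(self.ca_coords) < 3:
            raise ValueError(f"chain {self.id!r}: fewer than 3 residues")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError(f"chain {self.id!r}: non-finite coordinates")
        if not self.residue_names:
            self.residue_names = ["UNK"] * len(self.ca_coords)
        if len(self.residue_names) != len(self.ca_coords):
            raise ValueError(f"chain {self.id!r}: residue names do not match coordinates")

    def __len__(self) -> int:
        return len(self.ca_coords)


class PairMatrix:
    """Labeled symmetric matrix of one metric's all-against-all values.

    Invariants (checked at construction): symmetry to 1e-6, the metric's
    required diagonal, and value range.  ``orientation`` is ``"similarity"``
    or ``"distance"``; converted matrices (see :func:`mpact.viz.to_distance`)
    keep the source metric name but flip the orientation.
    """

    def __init__(
        self,
        labels: list[str],
        values: np.ndarray,
        metric: str,
        orientation: str | None = None,
    ) -> None:
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        labels = [str(x) for x in labels]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in matrix")
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} labels")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite matrix values")
        if np.max(np.abs(values - values.T), initial=0.0) > 1e-6:
            raise ValueError("matrix asymmetric beyond 1e-6")
        values = (values + values.T) / 2.0

        spec = METRICS[metric]
        self.orientation = orientation or spec["orientation"]
        if self.orientation not in ("similarity", "distance"):
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.orientation == spec["orientation"]:
            diag, (lo, hi) = spec["diag"], spec["range"]
            lo_ok = np.min(values, initial=diag) >= lo - 1e-9
            hi_ok = np.max(values, initial=diag) <= hi + 1e-9
        else:  # similarity metric converted to distance scale
            diag, lo_ok, hi_ok = 0.0, np.min(values, initial=0) >= -1e-9, True
        if not (lo_ok and hi_ok):
            raise ValueError(f"values out of range for metric {metric!r}")
        if np.max(np.abs(np.diag(values) - diag), initial=0.0) > 1e-6:
            raise ValueError(f"diagonal must be {diag} for metric {metric!r}")
        np.fill_diagonal(values, diag)

        self.labels = labels
        self.values = values
        self.metric = metric

    # -- convenience -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle (unordered pair) values as a flat array."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: list[str]) -> "PairMatrix":
        if sorted(labels) != sorted(self.labels):
            raise ValueError("reorder labels must be a permutation of matrix labels")
        idx = [self.labels.index(x) for x in labels]
        return PairMatrix(labels, self.values[np.ix_(idx, idx)], self.metric, self.orientation)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PairMatrix(metric={self.metric!r}, n={self.n}, orientation={self.orientation!r})"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _read_fasta_records(path, alphabet: str, aligned: bool, permissive: bool) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if permissive:
            valid = ALPHABETS[alphabet] | ({GAP} if aligned else set())
            sub = _PERMISSIVE_SUB[alphabet]
            residues = "".join(c if c in valid else sub for c in residues)
        desc = rec.description.split(None, 1)
        records.append(
            SequenceRecord(
                id=rec.id,
                alphabet=alphabet,
                residues=residues,
                description=desc[1] if len(desc) > 1 else "",
                aligned=aligned,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_fasta(path, alphabet: str, permissive: bool = False) -> list[SequenceRecord]:
    """Read unaligned FASTA; one record per entry, order preserved.

    Strict by default: a character outside the declared alphabet is a hard
    error naming the record and position.  With ``permissive=True`` unknown
    characters are mapped to N (nucleotide) or X (amino acid) instead.
    """
    return _read_fasta_records(path, alphabet, aligned=False, permissive=permissive)


def write_fasta(records: list[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_msa(path, alphabet: str, permissive: bool = False) -> list[SequenceRecord]:
    """Read an aligned FASTA (gap ``'-'`` allowed); rows must be equal length."""
    records = _read_fasta_records(path, alphabet, aligned=True, permissive=permissive)
    length = len(records[0].residues)
    ragged = [r.id for r in records if len(r.residues) != length]
    if ragged:
        raise ValueError(f"ragged MSA rows (length != {length}): {', '.join(ragged)}")
    return records


write_msa = write_fasta


# ---------------------------------------------------------------------------
# PDB Cα extraction
# ---------------------------------------------------------------------------


def read_pdb_ca(path, chain_id: str | None = None) -> StructureChain:
    """Extract the Cα trace of one chain from a PDB file.

    Uses MODEL 1 only; if ``chain_id`` is omitted the first chain with CA
    atoms is used.  Alternate locations are resolved to the highest-occupancy
    conformer (ties broken in favour of altloc 'A'); insertion-coded residues
    are kept as distinct residues.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("s", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"no models in PDB file {path}") from None

    chains = [c for c in model if chain_id is None or c.id == chain_id]
    if chain_id is not None and not chains:
        raise ValueError(f"chain {chain_id!r} not found in {path}")

    for chain in chains:
        coords, names = [], []
        for residue in chain:
            if residue.id[0] != " ":  # skip HETATM / water
                continue
            if "CA" not in residue:
                continue
            atom = residue["CA"]
            if atom.is_disordered():
                alts = sorted(
                    atom.disordered_get_list(),
                    key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                )
                atom = alts[0]
            coords.append(atom.get_coord())
            names.append(residue.get_resname())
        if coords:
            if len(coords) < 3:
                raise ValueError(f"chain {chain.id!r} in {path}: fewer than 3 CA residues")
            return StructureChain(id=str(path_stem(path)), ca_coords=np.array(coords), residue_names=names)
    raise ValueError(f"no CA atoms found in {path}")


def path_stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------


def write_matrix(matrix: PairMatrix, path) -> None:
    """Write a PairMatrix as TSV: '#metric=' / '#orientation=' comment header,
    then a label header row and one labeled row per record, values to 4
    decimals."""
    with open(path, "w") as fh:
        fh.write(f"#metric={matrix.metric}\n")
        fh.write(f"#orientation={matrix.orientation}\n")
        fh.write("\t" + "\t".join(matrix.labels) + "\n")
        for label, row in zip(matrix.labels, matrix.values):
            fh.write(label + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")


def read_matrix(path) -> PairMatrix:
    """Read a TSV matrix written by :func:`write_matrix`; restores labels,
    the metric tag, orientation and symmetry, enforcing all invariants."""
    metric = orientation = None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = []
    for ln in lines:
        if ln.startswith("#metric="):
            metric = ln.split("=", 1)[1].strip()
        elif ln.startswith("#orientation="):
            orientation = ln.split("=", 1)[1].strip()
        elif ln.strip():
            body.append(ln)
    if metric is None:
        raise ValueError(f"{path}: missing '#metric=' header")
    if not body:
        raise ValueError(f"{path}: empty matrix")
    header = body[0].split("\t")
    col_labels = header[1:] if header[0] == "" else header
    rows, row_labels = [], []
    for ln in body[1:]:
        parts = ln.split("\t")
        row_labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    if len(row_labels) != len(col_labels):
        raise ValueError(
            f"{path}: non-square matrix ({len(row_labels)} rows, {len(col_labels)} columns)"
        )
    if row_labels != col_labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    values = np.array(rows, dtype=float)
    return PairMatrix(row_labels, values, metric, orientation)


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def read_newick(path_or_string, rooted: bool | None = None) -> Tree:
    """Read a Newick tree (file path or literal string).

    Unbalanced parentheses or other syntax errors raise a parse error with
    position information (propagated from the underlying parser).
    """
    s = str(path_or_string)
    kwargs = {}
    if rooted is not None:
        kwargs["rooting"] = "force-rooted" if rooted else "force-unrooted"
    if "(" in s or ";" in s:
        tree = dendropy.Tree.get(data=s, schema="newick", **kwargs)
    else:
        tree = dendropy.Tree.get(path=s, schema="newick", **kwargs)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: Tree, path) -> None:
    """Write standard Newick with branch lengths to 6 decimals."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    with open(path, "w") as fh:
        fh.write(s)


def newick_string(tree: Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    ).strip()
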