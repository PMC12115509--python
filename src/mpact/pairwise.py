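"""Affine-gap Needleman–Wunsch global alignment and identity / similarity
percentages, for nucleotide, amino-acid and 3Di sequences.

Defaults mirror the EMBOSS needle program: gap open 10.0, gap extend 0.5,
end gaps unpenalized, BLOSUM62 for proteins and the EDNAFULL (NUC.4.4)
matrix for nucleotides.  A gap run of length L is charged
``open + (L-1)·extend``; when end gaps are free, leading and trailing runs
cost nothing.  Traceback ties are broken deterministically
(diagonal > up > left) so outputs are bit-stable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqio import ALPHABETS, GAP, PairMatrix, SequenceRecord

__all__ = [
    "SubstitutionMatrix",
    "AlignmentResult",
    "nw_align",
    "percent_identity",
    "percent_similarity",
    "all_vs_all_sequences",
    "threedi_similarity",
    "default_matrix",
]

NEG = -1.0e30  # effectively -inf for the DP

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


# ---------------------------------------------------------------------------
# Substitution matrices
# ---------------------------------------------------------------------------


class SubstitutionMatrix:
    """Symmetric residue substitution scores over one alphabet.

    Scores are stored as a dense k×k array over ``letters``; ``score(a, b)``
    is defined for every ordered pair of alphabet characters, including
    ambiguity codes.
    """

    def __init__(self, alphabet: str, letters: str, scores: np.ndarray, name: str = "") -> None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(letters), len(letters)):
            raise ValueError("score array shape does not match letters")
        if not np.allclose(scores, scores.T):
            raise ValueError(f"substitution matrix {name!r} is not symmetric")
        missing = ALPHABETS[alphabet] - set(letters)
        if missing:
            raise ValueError(f"matrix {name!r} missing letters {sorted(missing)}")
        self.alphabet = alphabet
        self.letters = letters
        self.scores = scores
        self.name = name
        self._index = {c: i for i, c in enumerate(letters)}

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self._index[a], self._index[b]])

    def encode(self, residues: str) -> np.ndarray:
        try:
            return np.array([self._index[c] for c in residues], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"character {exc.args[0]!r} not in matrix {self.name!r}") from None

    def pair_scores(self, a: str, b: str) -> np.ndarray:
        """Dense |a|×|b| score table for one sequence pair."""
        ia, ib = self.encode(a), self.encode(b)
        return self.scores[np.ix_(ia, ib)]

    # -- bundled matrices --------------------------------------------------

    @classmethod
    def _from_biopython(cls, base, alphabet: str, expansions: dict[str, str], name: str):
        """Extend a Biopython array with extra letters scored as the
        elementwise minimum over their expansion sets (keeps symmetry and a
        positive diagonal)."""
        base_letters = "".join(base.alphabet)
        letters = base_letters + "".join(expansions)
        k = len(letters)
        scores = np.zeros((k, k))
        scores[: len(base_letters), : len(base_letters)] = np.asarray(base)

        def expand(c: str) -> str:
            return expansions.get(c, c)

        for i, ci in enumerate(letters):
            for j, cj in enumerate(letters):
                if i < len(base_letters) and j < len(base_letters):
                    continue
                scores[i, j] = min(
                    base[x, y] for x in expand(ci) for y in expand(cj)
                )
        return cls(alphabet, letters, scores, name)

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        """BLOSUM62, extended to U (as C), O (as K) and J (min of I/L)."""
        from Bio.Align import substitution_matrices

        base = substitution_matrices.load("BLOSUM62")
        return cls._from_biopython(
            base, "amino_acid", {"U": "C", "O": "K", "J": "IL"}, "blosum62"
        )

    @classmethod
    def dnafull(cls) -> "SubstitutionMatrix":
        """EDNAFULL-equivalent (NUC.4.4) with U scored as T."""
        from Bio.Align import substitution_matrices

        base = substitution_matrices.load("NUC.4.4")
        return cls._from_biopython(base, "nucleotide", {"U": "T"}, "dnafull")

    @classmethod
    def threedi(cls) -> "SubstitutionMatrix":
        """The Foldseek 3Di structural-alphabet substitution matrix
        (bundled with biotite)."""
        import biotite.sequence.align as _align

        m = _align.SubstitutionMatrix.std_3di_matrix()
        letters = "".join(s.upper() for s in m.get_alphabet1())
        return cls("threedi", letters, np.asarray(m.score_matrix(), dtype=float), "threedi")

    @classmethod
    def from_emboss_file(cls, path, alphabet: str, name: str | None = None) -> "SubstitutionMatrix":
        """Read a matrix in EMBOSS/NCBI text format (user override hook)."""
        from Bio.Align import substitution_matrices

        base = substitution_matrices.read(str(path))
        letters = "".join(base.alphabet)
        return cls(alphabet, letters, np.asarray(base, dtype=float), name or str(path))

    def write_emboss_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.name}\n")
            fh.write("   " + "  ".join(self.letters) + "\n")
            for c, row in zip(self.letters, self.scores):
                fh.write(c + " " + " ".join(f"{v:3.0f}" for v in row) + "\n")


_DEFAULTS: dict[str, SubstitutionMatrix] = {}


def default_matrix(alphabet: str) -> SubstitutionMatrix:
    if alphabet not in _DEFAULTS:
        maker = {
            "amino_acid": SubstitutionMatrix.blosum62,
            "nucleotide": SubstitutionMatrix.dnafull,
            "threedi": SubstitutionMatrix.threedi,
        }[alphabet]
        _DEFAULTS[alphabet] = maker()
    return _DEFAULTS[alphabet]


# ---------------------------------------------------------------------------
# DP kernel (Gotoh three-state affine alignment)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _gotoh_kernel(S, go, ge, end_free):  # pragma: no cover - exercised via nw_align
    """Three-state affine DP.  States: 0 = match/mismatch (diagonal),
    1 = gap in b (up, consumes a), 2 = gap in a (left, consumes b).
    Returns (score, ptrM, ptrX, ptrY, end_state)."""
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        if end_free:
            X[i, 0] = 0.0
        else:
            X[i, 0] = -(go + (i - 1) * ge)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        if end_free:
            Y[0, j] = 0.0
        else:
            Y[0, j] = -(go + (j - 1) * ge)
        pY[0, j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # diagonal state: tie preference M > X > Y
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = ptr

            # gap in b (consumes a); free in the last column when end_free
            if end_free and j == m:
                op = 0.0
                ex = 0.0
            else:
                op = go
                ex = ge
            best = M[i - 1, j] - op
            ptr = 0
            if X[i - 1, j] - ex > best:
                best = X[i - 1, j] - ex
                ptr = 1
            if Y[i - 1, j] - op > best:
                best = Y[i - 1, j] - op
                ptr = 2
            X[i, j] = best
            pX[i, j] = ptr

            # gap in a (consumes b); free in the last row when end_free
            if end_free and i == n:
                op = 0.0
                ex = 0.0
            else:
                op = go
                ex = ge
            best = M[i, j - 1] - op
            ptr = 0
            if X[i, j - 1] - op > best:
                best = X[i, j - 1] - op
                ptr = 1
            if Y[i, j - 1] - ex > best:
                best = Y[i, j - 1] - ex
                ptr = 2
            Y[i, j] = best
            pY[i, j] = ptr

    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    return score, pM, pX, pY, state


# ---------------------------------------------------------------------------
# Alignment result and public operations
# ---------------------------------------------------------------------------


@dataclass
class AlignmentResult:
    """A global alignment with its score and extracted percentages.

    ``identity_pct`` counts exact residue matches, ``similarity_pct`` counts
    columns whose substitution score is positive; both use the full alignment
    length (gap columns included) as denominator, the EMBOSS convention.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    gaps: int


def nw_align(
    a: SequenceRecord,
    b: SequenceRecord,
    m: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    end_gaps_penalized: bool = False,
) -> AlignmentResult:
    """Optimal global alignment of two records under affine gap penalties."""
    if a.alphabet != b.alphabet:
        raise ValueError(f"alphabet mismatch: {a.id} is {a.alphabet}, {b.id} is {b.alphabet}")
    if m is None:
        m = default_matrix(a.alphabet)
    if m.alphabet != a.alphabet:
        raise ValueError(f"matrix {m.name!r} is for {m.alphabet}, records are {a.alphabet}")
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequence")
    if not (gap_open >= gap_extend >= 0):
        raise ValueError("require gap_open >= gap_extend >= 0")

    S = m.pair_scores(a.residues, b.residues)
    score, pM, pX, pY, state = _gotoh_kernel(
        S, float(gap_open), float(gap_extend), not end_gaps_penalized
    )

    # traceback
    i, j = len(a.residues), len(b.residues)
    cols_a: list[str] = []
    cols_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            cols_a.append(a.residues[i - 1])
            cols_b.append(b.residues[j - 1])
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            cols_a.append(a.residues[i - 1])
            cols_b.append(GAP)
            state = pX[i, j]
            i -= 1
        else:
            cols_a.append(GAP)
            cols_b.append(b.residues[j - 1])
            state = pY[i, j]
            j -= 1
    aligned_a = "".join(reversed(cols_a))
    aligned_b = "".join(reversed(cols_b))

    result = AlignmentResult(aligned_a, aligned_b, float(score), 0.0, 0.0, 0)
    result.gaps = sum(1 for x, y in zip(aligned_a, aligned_b) if x == GAP or y == GAP)
    result.identity_pct = percent_identity(result)
    result.similarity_pct = percent_similarity(result, m)
    return result


def percent_identity(r: AlignmentResult) -> float:
    """100 · (columns with equal non-gap residues) / alignment length."""
    length = len(r.aligned_a)
    matches = sum(1 for x, y in zip(r.aligned_a, r.aligned_b) if x == y and x != GAP)
    return 100.0 * matches / length


def percent_similarity(r: AlignmentResult, m: SubstitutionMatrix) -> float:
    """100 · (columns with two non-gap residues scoring > 0) / alignment length."""
    length = len(r.aligned_a)
    similar = sum(
        1
        for x, y in zip(r.aligned_a, r.aligned_b)
        if x != GAP and y != GAP and m.score(x, y) > 0
    )
    return 100.0 * similar / length


def _check_records(records: list[SequenceRecord]) -> None:
    if len(records) < 2:
        raise ValueError("need at least 2 records for all-against-all comparison")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in dataset")
    alphabets = {r.alphabet for r in records}
    if len(alphabets) > 1:
        raise ValueError(f"mixed alphabets in dataset: {sorted(alphabets)}")


def all_vs_all_sequences(
    records: list[SequenceRecord],
    m: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    end_gaps_penalized: bool = False,
    on_pair=None,
) -> tuple[PairMatrix, PairMatrix]:
    """All-against-all alignment: n(n−1)/2 alignments, each computed once.

    Returns (identity matrix, similarity matrix) with label order equal to
    input order.  ``on_pair`` is an optional callback ``(id_a, id_b, result)``
    used for instrumentation.
    """
    _check_records(records)
    if m is None:
        m = default_matrix(records[0].alphabet)
    n = len(records)
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        try:
            r = nw_align(records[i], records[j], m, gap_open, gap_extend, end_gaps_penalized)
        except Exception as exc:
            raise RuntimeError(
                f"alignment failed for pair ({records[i].id}, {records[j].id}): {exc}"
            ) from exc
        ident[i, j] = ident[j, i] = r.identity_pct
        simil[i, j] = simil[j, i] = r.similarity_pct
        if on_pair is not None:
            on_pair(records[i].id, records[j].id, r)
    labels = [r.id for r in records]
    return (
        PairMatrix(labels, ident, "identity_pct"),
        PairMatrix(labels, simil, "similarity_pct"),
    )


def threedi_similarity(
    records: list[SequenceRecord],
    m: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    end_gaps_penalized: bool = False,
) -> PairMatrix:
    """All-against-all 3Di-character similarity under the 3Di matrix."""
    _check_records(records)
    bad = [r.id for r in records if r.alphabet != "threedi"]
    if bad:
        raise ValueError(f"records not in 3Di alphabet: {', '.join(bad)}")
    if m is None:
        m = default_matrix("threedi")
    _, simil = all_vs_all_sequences(records, m, gap_open, gap_extend, end_gaps_penalized)
    return PairMatrix(simil.labels, simil.values, "threedi_similarity_pct")
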