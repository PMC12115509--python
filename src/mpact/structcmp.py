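"""Structure comparison: Kabsch superposition, TM-score with average-length
normalization, and an iterative TM-align-style heuristic aligner.

The TM-score of an aligned residue pairing is

    TM = (1/L_norm) · Σ_i 1 / (1 + (d_i/d0(L_norm))²)

with d_i the Cα–Cα distance of pair i after superposition and
d0(L) = 1.24·(L−15)^⅓ − 1.8 (floored at 0.5).  Scores are normalized by the
average length of the two chains, which makes the all-against-all matrix
symmetric in argument order by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqio import PairMatrix, StructureChain

__all__ = [
    "SuperpositionResult",
    "kabsch",
    "d0",
    "tm_score",
    "align_structures",
    "all_vs_all_structures",
]

#: DP gap penalty (d0-scaled score units) and refinement iteration cap.
GAP_PENALTY = 0.6
MAX_REFINE_ITER = 30


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of P onto Q (SVD solution).

    Returns (rotation, translation, rmsd) such that ``P @ rotation.T +
    translation`` minimizes the RMSD to Q over proper rotations (reflections
    excluded).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be (n, 3); got {P.shape} and {Q.shape}")
    if len(P) < 2:
        raise ValueError("need at least 2 points to superpose")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(Q))):
        raise ValueError("non-finite coordinates")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    if sign == 0:  # rank-deficient (collinear/planar); keep a proper rotation
        sign = 1.0
    R = Vt.T @ np.diag([1.0, 1.0, sign]) @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def d0(L_norm: int) -> float:
    """TM-score distance scale d0(L) = 1.24·(L−15)^⅓ − 1.8, floored at 0.5 Å."""
    if L_norm < 1:
        raise ValueError("L_norm must be >= 1")
    if L_norm <= 21:
        return 0.5
    return max(1.24 * (L_norm - 15.0) ** (1.0 / 3.0) - 1.8, 0.5)


# ---------------------------------------------------------------------------
# TM-score over a fixed pairing
# ---------------------------------------------------------------------------


def _check_pairs(pairs, la: int, lb: int) -> list[tuple[int, int]]:
    pairs = [(int(i), int(j)) for i, j in pairs]
    if not pairs:
        raise ValueError("empty alignment pair list")
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i2 <= i1 or j2 <= j1:
            raise ValueError("aligned pairs must be strictly increasing in both indices")
    if pairs[0][0] < 0 or pairs[-1][0] >= la or pairs[0][1] < 0 or pairs[-1][1] >= lb:
        raise ValueError("pair index out of range")
    return pairs


def _tm_from_distances(dists: np.ndarray, L_norm: int) -> float:
    return float(np.sum(1.0 / (1.0 + (dists / d0(L_norm)) ** 2)) / L_norm)


def _pair_distances(A, B, pairs, R, t) -> np.ndarray:
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    moved = A[ia] @ R.T + t
    return np.sqrt(np.sum((moved - B[ib]) ** 2, axis=1))


def tm_score(
    A: StructureChain,
    B: StructureChain,
    pairs: list[tuple[int, int]],
    L_norm: int | None = None,
) -> float:
    """TM-score of a fixed sequential pairing, maximized over superpositions.

    The superposition is chosen by iterative refinement over subsets of the
    pairs (seed fragments of decreasing length; each seed is extended by
    re-superposing on the pairs currently within a distance cutoff), and the
    best score found is returned.  ``L_norm`` defaults to the rounded
    average chain length.
    """
    if L_norm is None:
        L_norm = int(np.floor((len(A) + len(B)) / 2.0 + 0.5))
    pairs = _check_pairs(pairs, len(A), len(B))
    PA, PB = A.ca_coords, B.ca_coords
    n = len(pairs)
    best = 0.0
    seed_lengths = sorted({n, max(n // 2, 3), max(n // 4, 3)}, reverse=True)
    cutoff0 = max(d0(L_norm), 4.5)
    for seed_len in seed_lengths:
        if seed_len > n:
            continue
        step = max(seed_len // 2, 1)
        for start in range(0, n - seed_len + 1, step):
            subset = pairs[start : start + seed_len]
            prev_sets = set()
            for _ in range(20):
                ia = np.array([p[0] for p in subset])
                ib = np.array([p[1] for p in subset])
                R, t, _ = kabsch(PA[ia], PB[ib])
                dists = _pair_distances(PA, PB, pairs, R, t)
                best = max(best, _tm_from_distances(dists, L_norm))
                cutoff = cutoff0
                sel = dists < cutoff
                while sel.sum() < 3:
                    cutoff += 0.5
                    sel = dists < cutoff
                new_subset = [p for p, keep in zip(pairs, sel) if keep]
                key = tuple(new_subset)
                if key in prev_sets:
                    break
                prev_sets.add(key)
                subset = new_subset
    return min(best, 1.0)


# ---------------------------------------------------------------------------
# TM-align-style heuristic alignment
# ---------------------------------------------------------------------------


@njit(cache=True)
def _tm_dp(score, gap):  # pragma: no cover - exercised via align_structures
    """NW DP with free end gaps and linear gap penalty on the TM similarity
    table; returns the traceback pointer matrix (0 diag, 1 up, 2 left)."""
    n, m = score.shape
    H = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        ptr[i, 0] = 1
    for j in range(1, m + 1):
        ptr[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + score[i - 1, j - 1]
            up = H[i - 1, j] - (0.0 if j == m else gap)
            left = H[i, j - 1] - (0.0 if i == n else gap)
            best = diag
            p = 0
            if up > best:
                best = up
                p = 1
            if left > best:
                best = left
                p = 2
            H[i, j] = best
            ptr[i, j] = p
    return ptr


def _dp_pairs(score: np.ndarray, gap: float) -> list[tuple[int, int]]:
    ptr = _tm_dp(score, gap)
    i, j = score.shape
    pairs = []
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0 and i > 0 and j > 0:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif p == 1 and i > 0:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


@dataclass
class SuperpositionResult:
    """Best structural alignment of two chains."""

    rotation: np.ndarray
    translation: np.ndarray
    aligned_pairs: list[tuple[int, int]]
    rmsd: float
    tm_score: float


def _refine(PA, PB, pairs, L_norm, max_iter=MAX_REFINE_ITER):
    """Iterate {superpose on pairs → TM similarity table → DP → new pairs}
    until the pair set repeats.  Returns (best_tm, best_pairs, R, t)."""
    dzero = d0(L_norm)
    best_tm, best_pairs, best_Rt = -1.0, None, None
    seen = set()
    for _ in range(max_iter):
        key = tuple(pairs)
        if key in seen or len(pairs) < 3:
            break
        seen.add(key)
        ia = np.array([p[0] for p in pairs])
        ib = np.array([p[1] for p in pairs])
        R, t, _ = kabsch(PA[ia], PB[ib])
        moved = PA @ R.T + t
        diff = moved[:, None, :] - PB[None, :, :]
        dmat = np.sqrt(np.sum(diff**2, axis=2))
        sim = 1.0 / (1.0 + (dmat / dzero) ** 2)
        tm = float(np.sum(sim[ia, ib]) / L_norm)
        if tm > best_tm:
            best_tm, best_pairs, best_Rt = tm, pairs, (R, t)
        pairs = _dp_pairs(sim, GAP_PENALTY)
    return best_tm, best_pairs, best_Rt


def align_structures(A: StructureChain, B: StructureChain) -> SuperpositionResult:
    """Best sequential structural alignment of two Cα chains.

    Seeds (gapless threadings at every offset, plus half-length fragment
    superpositions) are each refined by iterating superposition → distance
    matrix → DP with score 1/(1+(d/d0)²) and gap penalty −0.6 until the pair
    set repeats; the highest-TM result is returned, TM normalized by the
    rounded average chain length.
    """
    la, lb = len(A), len(B)
    if la < 5 or lb < 5:
        raise ValueError("structure alignment requires chains of length >= 5")
    PA, PB = A.ca_coords, B.ca_coords
    L_norm = int(np.floor((la + lb) / 2.0 + 0.5))

    # cheap scan of gapless threadings, keep the top seeds for full refinement
    seeds: list[tuple[float, list[tuple[int, int]]]] = []
    for offset in range(-(la - 5), lb - 4):
        i0, j0 = max(0, -offset), max(0, offset)
        length = min(la - i0, lb - j0)
        if length < 5:
            continue
        pairs = [(i0 + k, j0 + k) for k in range(length)]
        ia = np.array([p[0] for p in pairs])
        ib = np.array([p[1] for p in pairs])
        R, t, _ = kabsch(PA[ia], PB[ib])
        dists = np.sqrt(np.sum((PA[ia] @ R.T + t - PB[ib]) ** 2, axis=1))
        seeds.append((_tm_from_distances(dists, L_norm), pairs))
    seeds.sort(key=lambda s: -s[0])
    candidates = [p for _, p in seeds[:5]]
    # fragment seeds: superpose half-length windows at a few anchor positions
    frag = max(min(la, lb) // 2, 5)
    for ai in {0, max((la - frag) // 2, 0), la - frag}:
        for bj in {0, max((lb - frag) // 2, 0), lb - frag}:
            candidates.append([(ai + k, bj + k) for k in range(frag)])

    best = None
    for pairs in candidates:
        tm, bp, Rt = _refine(PA, PB, pairs, L_norm)
        if bp is None:
            continue
        if best is None or tm > best[0]:
            best = (tm, bp, Rt)
    if best is None or len(best[1]) < 5:
        raise ValueError(f"no structural alignment with >= 5 pairs for ({A.id}, {B.id})")

    tm, pairs, (R, t) = best
    # final polish: maximize TM over superposition subsets of the final pairing
    tm = max(tm, tm_score(A, B, pairs, L_norm))
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    R, t, rmsd = kabsch(PA[ia], PB[ib])
    return SuperpositionResult(
        rotation=R,
        translation=t,
        aligned_pairs=pairs,
        rmsd=rmsd,
        tm_score=min(tm, 1.0),
    )


def all_vs_all_structures(chains: list[StructureChain]) -> PairMatrix:
    """Symmetric TM-score matrix, computed once per unordered pair (the
    average-length normalization makes the score orientation-free)."""
    if len(chains) < 2:
        raise ValueError("need at least 2 chains")
    ids = [c.id for c in chains]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate chain ids")
    n = len(chains)
    values = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        try:
            res = align_structures(chains[i], chains[j])
        except Exception as exc:
            raise RuntimeError(f"structure comparison failed for pair ({ids[i]}, {ids[j]}): {exc}") from exc
        values[i, j] = values[j, i] = res.tm_score
    return PairMatrix(ids, values, "tm_score")
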