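"""Locating a tandem-repeat region within a read.

Two stages. A coarse stage collects exact k-mer matches as anchors and
chains colinear anchors by dynamic programming; the span of the best chain
(padded by 20% on each side) is the candidate substring R'. A fine stage
runs a diagonal-free self local alignment on R': Smith-Waterman against
itself, restricted to the strict upper triangle of the table so a position
can never align to itself. If R' contains m tandem copies of a unit, the
optimal off-diagonal path aligns copy r to copy r+1 and its footprint
delimits the repeat region S; on repeat-free sequence the optimal path is
short and the region is rejected.

The full DP table is kept: its significant traceback paths are the raw
material for the equivalence-class construction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "ScoringScheme",
    "Anchor",
    "RepeatRegion",
    "find_anchors",
    "find_candidate_region",
    "self_alignment_table",
    "diagonal_free_align",
    "traceback_step",
]

_N_CODE = ord("N")


@dataclass(frozen=True)
class ScoringScheme:
    """Linear-gap local alignment scores (match > 0 > mismatch, gap)."""

    match: int = 2
    mismatch: int = -3
    gap: int = -4

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch and self.gap < 0):
            raise ValueError("require match > 0 > mismatch and gap < 0")


@dataclass(frozen=True)
class Anchor:
    """Two equal k-mers starting at 1-based positions x < y of the read."""

    x: int
    y: int
    k: int


@dataclass(frozen=True)
class RepeatRegion:
    """A substring of a read hypothesized to contain tandem copies."""

    read_id: str
    start: int  # 1-based inclusive
    end: int
    seq: str


def find_anchors(seq: str, k: int, max_occurrences: int = 100) -> List[Anchor]:
    """All ordered pairs of equal k-mers in ``seq`` (N-containing k-mers and
    k-mers occurring more than ``max_occurrences`` times are skipped)."""
    positions: dict = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        positions.setdefault(kmer, []).append(i + 1)
    anchors: List[Anchor] = []
    for kmer, pos in positions.items():
        if len(pos) < 2 or len(pos) > max_occurrences or "N" in kmer:
            continue
        for a in range(len(pos)):
            for b in range(a + 1, len(pos)):
                anchors.append(Anchor(pos[a], pos[b], k))
    return anchors


def _chain_anchors(
    anchors: List[Anchor],
    gap_bp_per_point: int = 50,
    band: int = 100,
    window_bp: int = 1000,
    max_lookback: int = 200,
) -> List[Anchor]:
    """Best colinear chain (x and y strictly increasing).

    Chain score is the anchor count minus one point per ``gap_bp_per_point``
    bp of offset discontinuity between consecutive anchors; transitions with
    offset jumps beyond ``band`` bp are disallowed. Predecessor search is
    banded for tractability; the coarse stage only needs rough localization.
    """
    if not anchors:
        return []
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].x, anchors[i].y))
    X = np.array([anchors[i].x for i in order], dtype=np.int64)
    Y = np.array([anchors[i].y for i in order], dtype=np.int64)
    n = len(order)
    score = np.ones(n)
    parent = np.full(n, -1, dtype=np.int64)
    count = np.ones(n, dtype=np.int64)
    for j in range(1, n):
        lo = int(np.searchsorted(X, X[j] - window_bp, side="left"))
        lo = max(lo, j - max_lookback)
        if lo >= j:
            continue
        dx = X[j] - X[lo:j]
        dy = Y[j] - Y[lo:j]
        jump = np.abs(dy - dx)
        ok = (dx > 0) & (dy > 0) & (jump <= band)
        if not ok.any():
            continue
        cand = score[lo:j] + 1.0 - jump / gap_bp_per_point
        cand[~ok] = -np.inf
        b = int(np.argmax(cand))
        if cand[b] > 1.0:
            score[j] = cand[b]
            parent[j] = lo + b
            count[j] = count[lo + b] + 1
    best = int(np.argmax(score))
    chain = []
    i = best
    while i >= 0:
        chain.append(anchors[order[i]])
        i = int(parent[i])
    chain.reverse()
    return chain


def find_candidate_region(read, k: int = 9, min_chain: int = 3) -> Tuple[int, int]:
    """Coarse repeat localization; returns a 1-based inclusive span.

    The span of the best anchor chain, extended by 20% of its length on each
    side (clipped to the read). Falls back to the whole read when the best
    chain has fewer than ``min_chain`` anchors.
    """
    seq = read.seq
    n = len(seq)
    if n < k:
        return 1, n
    chain = _chain_anchors(find_anchors(seq, k))
    if len(chain) < min_chain:
        return 1, n
    lo = min(a.x for a in chain)
    hi = max(a.y + a.k - 1 for a in chain)
    ext = int(round(0.2 * (hi - lo + 1)))
    return max(1, lo - ext), min(n, hi + ext)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def self_alignment_table(seq: str, scoring: ScoringScheme = ScoringScheme()) -> np.ndarray:
    """Diagonal-free self local alignment table D, 1-based, (n+1)x(n+1).

    D[i, j] for 1 <= i < j <= n is the best local alignment score of a path
    ending with positions i and j aligned (or gapped); the diagonal and the
    lower triangle stay zero, which enforces that no cell on or below the
    diagonal is ever used. Filled by anti-diagonals so each wavefront is a
    single vectorized update. N acts as a universal mismatch.
    """
    n = len(seq)
    code = _encode(seq)
    D = np.zeros((n + 1, n + 1), dtype=np.int32)
    if n < 2:
        return D
    match, mismatch, gap = scoring.match, scoring.mismatch, scoring.gap
    for d in range(3, 2 * n):  # d = i + j
        i_lo = max(1, d - n)
        i_hi = (d - 1) // 2
        if i_lo > i_hi:
            continue
        ii = np.arange(i_lo, i_hi + 1)
        jj = d - ii
        ci = code[ii - 1]
        cj = code[jj - 1]
        sub = np.where((ci == cj) & (ci != _N_CODE), match, mismatch).astype(np.int32)
        best = D[ii - 1, jj - 1] + sub
        np.maximum(best, D[ii - 1, jj] + gap, out=best)
        np.maximum(best, D[ii, jj - 1] + gap, out=best)
        np.maximum(best, 0, out=best)
        D[ii, jj] = best
    return D


def traceback_step(
    D: np.ndarray, code: np.ndarray, scoring: ScoringScheme, i: int, j: int
) -> Tuple[int, int]:
    """Deterministic predecessor of cell (i, j): diagonal, then up, then left.

    ``code`` must be indexable so that ``code[i]`` is the residue of table
    row/column ``i`` (1-based).
    """
    v = D[i, j]
    ci, cj = code[i], code[j]
    sub = scoring.match if (ci == cj and ci != _N_CODE) else scoring.mismatch
    if v == D[i - 1, j - 1] + sub:
        return i - 1, j - 1
    if v == D[i - 1, j] + scoring.gap:
        return i - 1, j
    if v == D[i, j - 1] + scoring.gap:
        return i, j - 1
    raise AssertionError(f"cell ({i},{j}) does not satisfy the local recurrence")


def _trace_optimal_path(
    D: np.ndarray, code: np.ndarray, scoring: ScoringScheme, p: int, q: int
) -> List[Tuple[int, int]]:
    """Cells of the optimal path ending at (p, q), first-to-last order."""
    cells = []
    i, j = p, q
    while i >= 1 and j >= 1 and D[i, j] > 0:
        cells.append((i, j))
        i, j = traceback_step(D, code, scoring, i, j)
    cells.reverse()
    return cells


def diagonal_free_align(
    seq: str,
    scoring: ScoringScheme = ScoringScheme(),
    min_align_len: int = 20,
) -> Tuple[np.ndarray, Optional[Tuple[int, int]]]:
    """Fine-stage repeat confirmation on a candidate substring.

    Returns the full DP table and, if the optimal path is long enough, the
    1-based span ``(a, d)`` of the repeat region: ``a`` is the first aligned
    position of the earlier segment and ``d`` the last aligned position of
    the later one, so the span covers both copies touched by the alignment.

    Acceptance: the optimal path aligning segment [a..b] to [c..d] is kept
    when the total number of residues it covers, (b-a+1) + (d-c+1), reaches
    ``min_align_len``. For m error-free copies of a unit U this measure is
    2(m-1)|U|, so the default of 20 admits three copies of a 7-mer.
    """
    D = self_alignment_table(seq, scoring)
    if D.size == 0 or D.max() <= 0:
        return D, None
    flat = int(np.argmax(D))  # row-major first among ties
    p, q = divmod(flat, D.shape[1])
    code = np.empty(len(seq) + 1, dtype=np.uint8)
    code[0] = 0
    code[1:] = _encode(seq)
    cells = _trace_optimal_path(D, code, scoring, p, q)
    a = min(i for i, _ in cells)
    b = max(i for i, _ in cells)
    c = min(j for _, j in cells)
    d = max(j for _, j in cells)
    if (b - a + 1) + (d - c + 1) >= min_align_len:
        return D, (a, d)
    return D, None
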