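"""Equivalence classes of positions within a repeat region.

Positions i and j of the region S are *equivalent* (i ~ j) when they
originate from the same position of the underlying repeat unit. The raw
evidence is the diagonal-free self-alignment table D: every significant
traceback path pairs one stretch of S with another at some multiple of the
unit length. The steps here are

1. collect local-maximum cells of D as path endpoints,
2. trace paths back through D and accumulate their scores into a sparse
   symmetric matrix M over position pairs,
3. refine M by mutual support of triples (if M[i,j], M[i,k], M[j,k] are all
   positive the three pairs reinforce each other) with row-mass
   normalization, for a fixed number of rounds,
4. extract non-overlapping high-mass paths from the refined matrix and merge
   positions along them into equivalence classes with a union-find,
   forbidding classes that would contain two positions closer than a
   minimum separation, and
5. elect a representative letter per class by majority vote (N never votes).
"""

from __future__ import annotations

import heapq
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from math import sqrt
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy.ndimage import maximum_filter

from .region_detect import ScoringScheme, traceback_step

__all__ = [
    "EquivMatrix",
    "AlignPath",
    "MatrixPath",
    "EquivClasses",
    "find_local_maxima",
    "build_initial_matrix",
    "refine_matrix",
    "extract_paths",
    "build_classes",
]

Cell = Tuple[int, int]


@dataclass
class EquivMatrix:
    """Sparse symmetric nonnegative weights over position pairs of S.

    Entries are stored once per unordered pair with 1 <= i < j <= n;
    ``entries[(i, j)]`` estimates, up to scale, how likely i ~ j is.
    """

    n: int
    entries: Dict[Cell, float] = field(default_factory=dict)

    def row_sums(self) -> Dict[int, float]:
        sums: Dict[int, float] = defaultdict(float)
        for (i, j), v in self.entries.items():
            sums[i] += v
            sums[j] += v
        return sums


@dataclass(frozen=True)
class AlignPath:
    """A traceback path of D: cells in first-to-last order and its score,
    the score differential between its endpoint and its termination cell."""

    cells: Tuple[Cell, ...]
    score: int


@dataclass(frozen=True)
class MatrixPath:
    """A monotone path of refined-matrix cells (steps move +1 in i and/or j)
    with score f(P) = sum of matrix values along it."""

    cells: Tuple[Cell, ...]
    score: float


@dataclass(frozen=True)
class EquivClasses:
    """A partition of positions 1..n with a representative letter per class.

    Classes are sorted by their smallest position; ``positions[c]`` is a
    sorted tuple and ``letters[c]`` its majority letter.
    """

    n: int
    positions: Tuple[Tuple[int, ...], ...]
    letters: Tuple[str, ...]

    @classmethod
    def from_partition(cls, parts: Iterable[Sequence[int]], seq: str) -> "EquivClasses":
        ordered = sorted((tuple(sorted(p)) for p in parts if p), key=lambda p: p[0])
        letters = tuple(_majority_letter(p, seq) for p in ordered)
        covered = [pos for p in ordered for pos in p]
        if sorted(covered) != list(range(1, len(seq) + 1)):
            raise ValueError("classes must partition positions 1..|S|")
        return cls(len(seq), tuple(ordered), letters)

    def class_of(self) -> np.ndarray:
        """Array mapping position (1-based index) to class index."""
        out = np.full(self.n + 1, -1, dtype=np.int64)
        for c, members in enumerate(self.positions):
            for p in members:
                out[p] = c
        return out

    def sizes(self) -> List[int]:
        return [len(p) for p in self.positions]


def _majority_letter(members: Sequence[int], seq: str) -> str:
    votes = Counter(seq[p - 1] for p in members if seq[p - 1] != "N")
    if not votes:
        return "N"
    top = max(votes.values())
    return min(letter for letter, c in votes.items() if c == top)


def find_local_maxima(D: np.ndarray, window: int = 7) -> List[Cell]:
    """Cells of D that are positive and maximal in the window centered on
    them, with plateau ties resolved by keeping only the row-major-first cell
    of each tied plateau. Windows are clipped at the table borders. Returned
    in row-major order (1-based cells; row/column 0 of D are excluded)."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    core = D[1:, 1:]
    if core.size == 0:
        return []
    filt = maximum_filter(core, size=window, mode="constant", cval=0)
    cand = np.argwhere((core > 0) & (core == filt))
    r = window // 2
    kept_mask = np.zeros(core.shape, dtype=bool)
    kept: List[Cell] = []
    for i, j in cand:
        i0, j0 = max(0, i - r), max(0, j - r)
        win_kept = kept_mask[i0 : i + r + 1, j0 : j + r + 1]
        win_vals = core[i0 : i + r + 1, j0 : j + r + 1]
        if np.any(win_kept & (win_vals == core[i, j])):
            continue
        kept_mask[i, j] = True
        kept.append((int(i) + 1, int(j) + 1))
    return kept


def build_initial_matrix(
    D: np.ndarray,
    seq: str,
    maxima: Sequence[Cell],
    scoring: ScoringScheme = ScoringScheme(),
    min_path_score: int = 25,
) -> Tuple[EquivMatrix, List[AlignPath]]:
    """Trace significant paths of D and write their scores into M.

    Endpoints are processed in descending order of D (ties row-major). Each
    traceback walks until it meets a cell already claimed by a kept path, a
    zero cell, or the table border; the path score is the score differential
    between the endpoint and the termination cell. Paths scoring below
    ``min_path_score`` are discarded (they typically arise from random
    matches); kept paths write their score to every cell on the path, a cell
    claimed twice keeping the larger value.

    ``seq`` must be the string whose positions index rows/columns 1..n of D.
    When D is a window of a larger table, row/column 0 may carry nonzero
    boundary scores; a traceback leaving the window terminates there and the
    differential accounts for the mass outside.
    """
    n = len(seq)
    code = np.empty(n + 1, dtype=np.uint8)
    code[0] = 0
    code[1:] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ordered = sorted(maxima, key=lambda c: (-int(D[c[0], c[1]]), c[0], c[1]))
    M: Dict[Cell, float] = {}
    paths: List[AlignPath] = []
    for p, q in ordered:
        cells: List[Cell] = []
        i, j = p, q
        while i >= 1 and j >= 1 and D[i, j] > 0 and (i, j) not in M:
            cells.append((i, j))
            i, j = traceback_step(D, code, scoring, i, j)
        score = int(D[p, q]) - int(D[i, j])
        if score < min_path_score or not cells:
            continue
        cells.reverse()
        paths.append(AlignPath(tuple(cells), score))
        for cell in cells:
            if M.get(cell, 0.0) < score:
                M[cell] = float(score)
    return EquivMatrix(n, M), paths


def refine_matrix(M: EquivMatrix, rounds: int = 5) -> EquivMatrix:
    """Iteratively reinforce mutually supporting triples.

    Per round: for every triple i < j < k whose three pairwise entries are
    all positive, add delta = min of the three entries (read from the
    round-start matrix) to each of the three entries; then rescale so each
    row's mass returns to its round-start sum. Because the matrix is stored
    once per unordered pair, a literal row-wise rescale would break symmetry,
    so each entry (i, j) is scaled by the geometric mean
    sqrt((A[i]/A'[i]) * (A[j]/A'[j])) of the two row factors, which reduces
    to the literal rule when the factors agree. Rows with zero round-start
    mass keep factor 1. An entry in no triple is untouched by the
    enhancement and only rescaled.
    """
    cur = {k: float(v) for k, v in M.entries.items()}
    for _ in range(rounds):
        adj: Dict[int, Dict[int, float]] = defaultdict(dict)
        for (i, j), v in cur.items():
            adj[i][j] = v
            adj[j][i] = v
        A = {i: sum(nb.values()) for i, nb in adj.items()}
        nxt = dict(cur)
        for (i, j), vij in cur.items():
            ni, nj = adj[i], adj[j]
            probe = ni if len(ni) <= len(nj) else nj
            for k in probe:
                if k <= j:
                    continue
                wik = ni.get(k)
                wjk = nj.get(k)
                if wik is None or wjk is None:
                    continue
                delta = min(vij, wik, wjk)
                nxt[(i, j)] += delta
                nxt[(i, k)] += delta
                nxt[(j, k)] += delta
        Ap: Dict[int, float] = defaultdict(float)
        for (i, j), v in nxt.items():
            Ap[i] += v
            Ap[j] += v
        factor = {i: (A[i] / Ap[i] if Ap[i] > 0 else 1.0) for i in Ap}
        cur = {
            (i, j): v * sqrt(factor[i] * factor[j]) for (i, j), v in nxt.items()
        }
    return EquivMatrix(M.n, cur)


_SUCC = ((1, 1), (1, 0), (0, 1))
_PRED = ((-1, -1), (-1, 0), (0, -1))


def extract_paths(M: EquivMatrix, min_score: float = 1.0) -> List[MatrixPath]:
    """Greedy peeling of non-overlapping monotone paths from the matrix.

    A dynamic program over the nonzero cells (moves from the diagonal,
    vertical and horizontal predecessors) scores the best path ending at
    each cell; the best path is peeled, its cells removed, and affected
    scores are repaired incrementally, until the best remaining path scores
    below ``min_score``. Returned paths are cell-disjoint.
    """
    live = {c: float(v) for c, v in M.entries.items() if v > 0}
    dp: Dict[Cell, float] = {}
    parent: Dict[Cell, Cell] = {}

    def relax(c: Cell) -> bool:
        i, j = c
        best = 0.0
        par = None
        for di, dj in _PRED:
            pc = (i + di, j + dj)
            v = dp.get(pc)
            if v is not None and pc in live and v > best:
                best = v
                par = pc
        nd = live[c] + best
        changed = dp.get(c) != nd
        dp[c] = nd
        if par is None:
            parent.pop(c, None)
        else:
            parent[c] = par
        return changed

    for c in sorted(live):  # row-major: all predecessors come earlier
        relax(c)
    heap = [(-v, c) for c, v in dp.items()]
    heapq.heapify(heap)
    out: List[MatrixPath] = []
    while heap:
        negv, end = heapq.heappop(heap)
        if end not in live or dp.get(end) != -negv:
            continue
        if -negv < min_score:
            break
        cells: List[Cell] = []
        cur = end
        while cur is not None:
            cells.append(cur)
            cur = parent.get(cur)
        cells.reverse()
        out.append(MatrixPath(tuple(cells), -negv))
        work: List[Cell] = []
        for cell in cells:
            del live[cell]
            dp.pop(cell, None)
            parent.pop(cell, None)
        for i, j in cells:
            for di, dj in _SUCC:
                sc = (i + di, j + dj)
                if sc in live:
                    heapq.heappush(work, sc)
        while work:
            sc = heapq.heappop(work)
            if sc not in live:
                continue
            if relax(sc):
                heapq.heappush(heap, (-dp[sc], sc))
                i, j = sc
                for di, dj in _SUCC:
                    nc = (i + di, j + dj)
                    if nc in live:
                        heapq.heappush(work, nc)
    return out


class _DSU:
    """Union-find over positions with sorted member lists per root."""

    def __init__(self, n: int):
        self.parent = list(range(n + 1))
        self.members = {i: [i] for i in range(1, n + 1)}

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def too_close(self, ra: int, rb: int, min_separation: int) -> bool:
        a, b = self.members[ra], self.members[rb]
        ia = ib = 0
        # merge-scan of two sorted lists, tracking the smallest cross gap
        while ia < len(a) and ib < len(b):
            if abs(a[ia] - b[ib]) <= min_separation:
                return True
            if a[ia] < b[ib]:
                ia += 1
            else:
                ib += 1
        return False

    def union(self, ra: int, rb: int) -> None:
        if len(self.members[ra]) < len(self.members[rb]):
            ra, rb = rb, ra
        merged = list(heapq.merge(self.members[ra], self.members[rb]))
        self.parent[rb] = ra
        self.members[ra] = merged
        del self.members[rb]


def build_classes(
    paths: Sequence[MatrixPath],
    M: EquivMatrix,
    seq: str,
    min_separation: int = 5,
) -> EquivClasses:
    """Merge positions along extracted paths into equivalence classes.

    Path cells are visited by descending refined weight (ties row-major);
    the union of i's and j's classes is skipped whenever the merged class
    would contain two positions at distance <= ``min_separation``. Every
    position of S appears in exactly one final class (uncovered positions
    stay singletons).
    """
    n = len(seq)
    dsu = _DSU(n)
    cells = [c for p in paths for c in p.cells]
    cells.sort(key=lambda c: (-M.entries[c], c[0], c[1]))
    for i, j in cells:
        ra, rb = dsu.find(i), dsu.find(j)
        if ra == rb:
            continue
        if dsu.too_close(ra, rb, min_separation):
            continue
        dsu.union(ra, rb)
    return EquivClasses.from_partition(dsu.members.values(), seq)
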