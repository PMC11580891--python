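"""Candidate repeat units from the class graph.

The equivalence classes become nodes of a weighted directed graph: an edge
A -> B counts positions i in A directly followed by a position of B (i+1 in
B), plus "gapped" successions i+2 in B where the skipped position i+1 forms
its own singleton class (the skip is likely an inserted base). Traversing
one unit of the repeat corresponds to a cycle in this graph, so the unit is
reconstructed from the cycle whose smallest edge weight (bottleneck) is
maximal among cycles whose classes cover more than half of the region.

Two recovery heuristics complement the cycle unit: over-combined classes
(abnormally large, merging positions from different unit offsets) are split
against their strongest in-edge for several rounds, each round contributing
another candidate; and for very short units (2-6 bp, below the separation
limit of class construction) the most frequent k-mer under rotation is
proposed directly. Step 4 selects among all candidates by tiled edit
distance, so a failed heuristic merely adds a losing candidate.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .equivalence import EquivClasses

__all__ = [
    "ClassGraph",
    "BottleneckCycle",
    "CandidateUnit",
    "build_class_graph",
    "find_bottleneck_cycle",
    "split_overcombined",
    "kmer_candidates",
    "canonical_rotation",
]

# exact cycle enumeration is used on subgraphs up to this many nodes
_EXACT_NODE_LIMIT = 20
_EXACT_CYCLE_CAP = 200_000
_GREEDY_STARTS = 5


@dataclass(frozen=True)
class CandidateUnit:
    """A candidate repeat unit and how it was produced: the bottleneck cycle
    ("graph"), a splitting round ("split-1".."split-5"), or the short-unit
    k-mer heuristic ("kmer-2".."kmer-6")."""

    seq: str
    provenance: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("candidate unit must be non-empty")


@dataclass
class ClassGraph:
    """Weighted directed graph over equivalence classes.

    Node c has ``sizes[c]`` member positions, representative ``letters[c]``
    and smallest member ``min_pos[c]``; ``edges[(a, b)]`` is the succession
    weight w(A, B) >= 1. ``total_positions`` is |S|.
    """

    sizes: List[int]
    letters: List[str]
    min_pos: List[int]
    edges: Dict[Tuple[int, int], int]
    total_positions: int


@dataclass(frozen=True)
class BottleneckCycle:
    """A simple cycle of class nodes with its bottleneck (minimum edge
    weight), total position coverage, and the spelled-out unit."""

    nodes: Tuple[int, ...]
    bottleneck: int
    coverage: int
    unit: str


def build_class_graph(classes: EquivClasses, seq: str) -> ClassGraph:
    """Count direct (i, i+1) and singleton-bridged (i, i+2) successions
    between distinct classes; pairs with total weight >= 1 become edges."""
    n = len(seq)
    cls_of = classes.class_of()
    sizes = classes.sizes()
    singleton = [s == 1 for s in sizes]
    edges: Dict[Tuple[int, int], int] = {}
    for i in range(1, n):
        a, b = int(cls_of[i]), int(cls_of[i + 1])
        if a != b:
            edges[(a, b)] = edges.get((a, b), 0) + 1
    for i in range(1, n - 1):
        mid = int(cls_of[i + 1])
        if not singleton[mid]:
            continue
        a, b = int(cls_of[i]), int(cls_of[i + 2])
        if a != b:
            edges[(a, b)] = edges.get((a, b), 0) + 1
    return ClassGraph(
        sizes=sizes,
        letters=list(classes.letters),
        min_pos=[p[0] for p in classes.positions],
        edges=edges,
        total_positions=n,
    )


def _canonical_cycle(nodes: Sequence[int]) -> Tuple[int, ...]:
    """Rotate a cycle so it starts at its smallest node id."""
    k = min(range(len(nodes)), key=lambda i: nodes[i])
    return tuple(nodes[k:]) + tuple(nodes[:k])


def _cycle_coverage(g: ClassGraph, nodes: Sequence[int]) -> int:
    return sum(g.sizes[c] for c in nodes)


def _best_cycle_exact(
    g: ClassGraph, sub: Dict[Tuple[int, int], int], required: float
) -> Optional[Tuple[int, ...]]:
    """Enumerate simple cycles of the thresholded subgraph and return the
    covering cycle with maximal coverage (deterministic tie-breaks), or None.
    Returns the sentinel () if enumeration blows past the cap."""
    G = nx.DiGraph()
    G.add_edges_from(sub.keys())
    best: Optional[Tuple[int, ...]] = None
    best_key = None
    count = 0
    for cyc in nx.simple_cycles(G):
        count += 1
        if count > _EXACT_CYCLE_CAP:
            return ()
        if len(cyc) < 2:
            continue
        cov = _cycle_coverage(g, cyc)
        if cov <= required:
            continue
        canon = _canonical_cycle(cyc)
        key = (-cov, len(canon), canon)
        if best_key is None or key < best_key:
            best_key = key
            best = canon
    return best


def _best_cycle_greedy(
    g: ClassGraph, sub: Dict[Tuple[int, int], int], required: float
) -> Optional[Tuple[int, ...]]:
    """Walk from each of the largest classes along maximum-weight out-edges
    until a node repeats; keep the best covering cycle discovered."""
    out_adj: Dict[int, List[Tuple[int, int]]] = {}
    nodes = set()
    for (a, b), w in sub.items():
        out_adj.setdefault(a, []).append((w, b))
        nodes.add(a)
        nodes.add(b)
    for lst in out_adj.values():
        lst.sort(key=lambda t: (-t[0], t[1]))
    starts = sorted(nodes, key=lambda c: (-g.sizes[c], c))[:_GREEDY_STARTS]
    best = None
    best_key = None
    for s in starts:
        seen = {s: 0}
        order = [s]
        cur = s
        for _ in range(len(nodes) + 1):
            outs = out_adj.get(cur)
            if not outs:
                break
            nxt = outs[0][1]
            if nxt in seen:
                cyc = order[seen[nxt] :]
                cov = _cycle_coverage(g, cyc)
                if cov > required:
                    canon = _canonical_cycle(cyc)
                    key = (-cov, len(canon), canon)
                    if best_key is None or key < best_key:
                        best_key = key
                        best = canon
                break
            seen[nxt] = len(order)
            order.append(nxt)
            cur = nxt
    return best


def _spell_unit(g: ClassGraph, nodes: Sequence[int]) -> str:
    start = min(range(len(nodes)), key=lambda i: g.min_pos[nodes[i]])
    ordered = tuple(nodes[start:]) + tuple(nodes[:start])
    return "".join(g.letters[c] for c in ordered)


def find_bottleneck_cycle(
    g: ClassGraph, required_coverage: Optional[float] = None
) -> Optional[BottleneckCycle]:
    """Maximum-bottleneck covering cycle of the class graph.

    Thresholds descend through the distinct edge weights; at each threshold
    only edges at least that heavy are kept, and the first threshold whose
    subgraph contains a simple cycle covering more than ``required_coverage``
    positions (default |S|/2) wins. Subgraphs with at most 20 nodes are
    searched exactly by cycle enumeration; larger ones by greedy
    maximum-weight walks from the largest classes. Returns None when no
    qualifying cycle exists at any threshold.

    The unit is spelled from the cycle's class letters, starting at the
    class containing the smallest position; rotation is immaterial
    downstream because selection and evaluation are rotation-aware.
    """
    if required_coverage is None:
        required_coverage = g.total_positions / 2
    if not g.edges:
        return None
    for w_star in sorted(set(g.edges.values()), reverse=True):
        sub = {e: w for e, w in g.edges.items() if w >= w_star}
        endpoints = {v for e in sub for v in e}
        if len(endpoints) <= _EXACT_NODE_LIMIT:
            cyc = _best_cycle_exact(g, sub, required_coverage)
            if cyc == ():  # enumeration overflow, degrade to the heuristic
                cyc = _best_cycle_greedy(g, sub, required_coverage)
        else:
            cyc = _best_cycle_greedy(g, sub, required_coverage)
        if cyc:
            bott = min(g.edges[(cyc[i], cyc[(i + 1) % len(cyc)])] for i in range(len(cyc)))
            return BottleneckCycle(
                nodes=cyc,
                bottleneck=bott,
                coverage=_cycle_coverage(g, cyc),
                unit=_spell_unit(g, cyc),
            )
    return None


def split_overcombined(
    classes: EquivClasses,
    seq: str,
    rounds: int = 5,
    required_coverage: Optional[float] = None,
) -> List[CandidateUnit]:
    """Split abnormally large classes and re-derive a unit per round.

    A class is a splitting target in round r when its size reaches
    theta_r = max(2*median - (r - 1), median + 1), the median taken over all
    current classes (singletons included); the admission size thus drops by
    one per round while staying above the median. Each target B is split
    against its maximum-weight in-edge (A, B): members of B that follow a
    member of A directly, or across a singleton gap, form B1 and the rest
    form B2; a split leaving either side empty is skipped. After each round
    the bottleneck-cycle search on the rebuilt graph contributes candidate
    ``split-r`` (rounds without a qualifying cycle contribute none).
    """
    parts: List[List[int]] = [list(p) for p in classes.positions]
    out: List[CandidateUnit] = []
    for r in range(1, rounds + 1):
        med = statistics.median(len(p) for p in parts)
        theta = max(2 * med - (r - 1), med + 1)
        targets = sorted(
            (frozenset(p) for p in parts if len(p) >= theta),
            key=lambda s: (-len(s), min(s)),
        )
        for target in targets:
            idx = next(
                (k for k, p in enumerate(parts) if len(p) == len(target) and set(p) == target),
                None,
            )
            if idx is None:
                continue
            cls = EquivClasses.from_partition(parts, seq)
            graph = build_class_graph(cls, seq)
            # class indices shift under from_partition's ordering; map back
            pos_to_sorted = {p[0]: k for k, p in enumerate(cls.positions)}
            b_sorted = pos_to_sorted[min(target)]
            in_edges = [
                (w, a) for (a, b), w in graph.edges.items() if b == b_sorted
            ]
            if not in_edges:
                continue
            w_max = max(w for w, _ in in_edges)
            a_sorted = min(a for w, a in in_edges if w == w_max)
            A = set(cls.positions[a_sorted])
            B = set(target)
            singles = {p[0] for p in cls.positions if len(p) == 1}
            B1 = {i + 1 for i in A if i + 1 in B} | {
                i + 2 for i in A if i + 2 in B and i + 1 in singles
            }
            B2 = B - B1
            if not B1 or not B2:
                continue
            parts[idx] = sorted(B1)
            parts.append(sorted(B2))
        cls = EquivClasses.from_partition(parts, seq)
        res = find_bottleneck_cycle(build_class_graph(cls, seq), required_coverage)
        if res is not None:
            out.append(CandidateUnit(res.unit, f"split-{r}"))
    return out


def canonical_rotation(s: str) -> str:
    """Lexicographically smallest rotation of ``s``."""
    return min(s[i:] + s[:i] for i in range(len(s)))


def kmer_candidates(seq: str) -> List[CandidateUnit]:
    """Most frequent k-mer of S under rotation, for k = 2..6.

    Every k-mer is mapped to its canonical (lexicographically smallest)
    rotation and the most frequent canonical form becomes candidate
    ``kmer-k`` (ties: alphabetically smallest form). Values of k longer
    than S contribute nothing.
    """
    out: List[CandidateUnit] = []
    for k in range(2, 7):
        if len(seq) < k:
            continue
        counts: Dict[str, int] = {}
        cache: Dict[str, str] = {}
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            canon = cache.get(kmer)
            if canon is None:
                canon = canonical_rotation(kmer)
                cache[kmer] = canon
            counts[canon] = counts.get(canon, 0) + 1
        best = min(counts, key=lambda c: (-counts[c], c))
        out.append(CandidateUnit(best, f"kmer-{k}"))
    return out
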