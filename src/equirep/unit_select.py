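"""Final unit selection by tiled edit distance.

Each candidate unit is concatenated enough times to reach the repeat-region
length, truncated exactly, and compared to the region by unit-cost edit
distance; the candidate with the lowest distance wins. Truncation makes the
distances comparable across unit lengths: a phase mismatch costs at most one
unit length and is shared by all candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .unit_graph import CandidateUnit

__all__ = ["SelectionResult", "edit_distance", "select_best", "PROVENANCE_ORDER"]

PROVENANCE_ORDER = (
    "graph",
    "split-1",
    "split-2",
    "split-3",
    "split-4",
    "split-5",
    "kmer-2",
    "kmer-3",
    "kmer-4",
    "kmer-5",
    "kmer-6",
)


@dataclass(frozen=True)
class SelectionResult:
    unit: CandidateUnit
    tiled_edit_distance: int
    copy_estimate: int


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (substitution/insertion/deletion = 1)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def tile_to_length(unit: str, length: int) -> str:
    reps = -(-length // len(unit))
    return (unit * reps)[:length]


def select_best(
    candidates: Sequence[CandidateUnit], seq: str
) -> Optional[SelectionResult]:
    """Pick the candidate whose tiling best matches the repeat region.

    Ties are broken by shorter unit (favoring the primitive period: a
    doubled unit tiles equally well), then by provenance order. Returns
    None for an empty candidate list. The copy estimate is |S|/|U| rounded
    half away from zero.
    """
    best = None
    best_key = None
    for order, cand in enumerate(candidates):
        dist = edit_distance(tile_to_length(cand.seq, len(seq)), seq)
        try:
            rank = PROVENANCE_ORDER.index(cand.provenance)
        except ValueError:
            rank = len(PROVENANCE_ORDER) + order
        key = (dist, len(cand.seq), rank)
        if best_key is None or key < best_key:
            best_key = key
            best = cand
    if best is None:
        return None
    return SelectionResult(
        unit=best,
        tiled_edit_distance=best_key[0],
        copy_estimate=int(len(seq) / len(best.seq) + 0.5),
    )
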