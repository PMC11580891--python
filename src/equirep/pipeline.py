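"""End-to-end tandem repeat detection on a read.

Orchestrates the four stages: coarse anchor-chain localization and
diagonal-free self-alignment (region), equivalence-class construction
(classes), candidate units from the class graph, class splitting and the
short-unit k-mer heuristic (candidates), and tiled edit-distance selection
(choice). ``infer_unit`` exposes the class/candidate/selection stages on a
known repeat region, which is also how worked examples with a given region
are run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .equivalence import (
    build_classes,
    build_initial_matrix,
    extract_paths,
    find_local_maxima,
    refine_matrix,
)
from .region_detect import (
    ScoringScheme,
    diagonal_free_align,
    find_candidate_region,
    self_alignment_table,
)
from .sequence_io import Prediction, Read
from .unit_graph import (
    CandidateUnit,
    build_class_graph,
    find_bottleneck_cycle,
    kmer_candidates,
    split_overcombined,
)
from .unit_select import SelectionResult, select_best

__all__ = ["DetectParams", "detect_read", "infer_unit"]


@dataclass(frozen=True)
class DetectParams:
    """Tunable knobs of the detector; defaults are the published operating
    point (see docs/methods.md for units and rationale)."""

    seed_k: int = 9
    min_chain: int = 3
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    min_align_len: int = 20
    window: int = 7
    min_path_score: int = 25
    refine_rounds: int = 5
    min_separation: int = 5
    split_rounds: int = 5


def infer_unit(
    seq: str,
    params: Optional[DetectParams] = None,
    table=None,
    offset: int = 1,
) -> Tuple[Optional[SelectionResult], List[CandidateUnit]]:
    """Infer the repeat unit of a known repeat region ``seq``.

    When ``table`` is given it must be the self-alignment table of a string
    containing ``seq`` starting at 1-based position ``offset``; the table is
    then windowed to the region rather than recomputed, and tracebacks that
    leave the window terminate at its border with the border score absorbed
    into the path-score differential. Returns the selection (None only when
    no candidate at all could be formed, i.e. |S| < 2) together with the
    full candidate list.
    """
    if params is None:
        params = DetectParams()
    n = len(seq)
    if table is None:
        table = self_alignment_table(seq, params.scoring)
        offset = 1
    window = table[offset - 1 : offset + n, offset - 1 : offset + n]
    maxima = find_local_maxima(window, params.window)
    matrix, _ = build_initial_matrix(
        window, seq, maxima, params.scoring, params.min_path_score
    )
    refined = refine_matrix(matrix, params.refine_rounds)
    paths = extract_paths(refined)
    classes = build_classes(paths, refined, seq, params.min_separation)

    candidates: List[CandidateUnit] = []
    graph = build_class_graph(classes, seq)
    cycle = find_bottleneck_cycle(graph)
    if cycle is not None:
        candidates.append(CandidateUnit(cycle.unit, "graph"))
    candidates.extend(split_overcombined(classes, seq, params.split_rounds))
    candidates.extend(kmer_candidates(seq))
    return select_best(candidates, seq), candidates


def detect_read(read: Read, params: Optional[DetectParams] = None) -> Prediction:
    """Full detection on one read; returns a no-repeat prediction when the
    self-alignment finds no sufficiently long off-diagonal structure."""
    if params is None:
        params = DetectParams()
    none = Prediction(read_id=read.id)
    if len(read.seq) < 2:
        return none
    cs, ce = find_candidate_region(read, params.seed_k, params.min_chain)
    segment = read.seq[cs - 1 : ce]
    table, span = diagonal_free_align(segment, params.scoring, params.min_align_len)
    # a region whose optimal alignment cannot clear the path-score threshold
    # would leave the evidence matrix empty: no repeat evidence at all
    if span is None or int(table.max()) < params.min_path_score:
        return none
    a, d = span
    region = segment[a - 1 : d]
    selection, _ = infer_unit(region, params, table=table, offset=a)
    if selection is None:
        return none
    return Prediction(
        read_id=read.id,
        unit=selection.unit.seq,
        unit_length=len(selection.unit.seq),
        region_start=cs - 1 + a,
        region_end=cs - 1 + d,
        copy_estimate=selection.copy_estimate,
        tiled_edit_distance=selection.tiled_edit_distance,
        provenance=selection.unit.provenance,
    )
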