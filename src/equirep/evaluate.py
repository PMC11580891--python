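"""Rotation-aware evaluation of predicted repeat units.

A predicted unit is correct up to rotation: the detector may start reading
the cycle anywhere. The headline metric is therefore the minimum edit
distance between the truth and any cyclic rotation of the prediction. For
data without ground-truth units, the semi-edit distance compares the input
sequence against the best-matching substring of a tiling of the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pandas as pd
import edlib

from .sequence_io import Prediction
from .unit_select import edit_distance

__all__ = [
    "EvalSummary",
    "rotation_aware_edit",
    "semi_edit_distance",
    "summarize_metrics",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class EvalSummary:
    """Per-setting summary of rotation-aware distances: exact matches,
    counts below 10% and 20% of the unit length (strict), and the mean."""

    n: int
    exact: int
    lt10: int
    lt20: int
    mean: float


def rotation_aware_edit(pred: str, truth: str) -> int:
    """Minimum edit distance between ``truth`` and any rotation of ``pred``."""
    if not pred or not truth:
        raise ValueError("sequences must be non-empty")
    seen = set()
    best = None
    for r in range(len(pred)):
        rot = pred[r:] + pred[:r]
        if rot in seen:
            continue
        seen.add(rot)
        d = edit_distance(rot, truth)
        if best is None or d < best:
            best = d
            if best == 0:
                break
    return best


def semi_edit_distance(tiled: str, query: str) -> int:
    """Smallest edit distance between any substring of ``tiled`` and
    ``query`` (semi-global alignment with free ends on ``tiled``)."""
    if not query:
        return 0
    if not tiled:
        return len(query)
    return edlib.align(query, tiled, mode="HW", task="distance")["editDistance"]


def summarize_metrics(distances: Sequence[int], unit_length: int) -> EvalSummary:
    """Exact / <10% / <20% counts (strict thresholds on the true unit
    length) and the mean distance."""
    if not distances:
        raise ValueError("distances must be non-empty")
    if unit_length < 1:
        raise ValueError("unit_length must be >= 1")
    n = len(distances)
    exact = sum(1 for d in distances if d == 0)
    lt10 = sum(1 for d in distances if d < 0.10 * unit_length)
    lt20 = sum(1 for d in distances if d < 0.20 * unit_length)
    return EvalSummary(n, exact, lt10, lt20, sum(distances) / n)


def evaluate_predictions(
    predictions: Sequence[Prediction],
    truths: Dict[str, str],
) -> pd.DataFrame:
    """Rotation-aware distance per read against ``truths`` (read_id -> true
    unit). A read with no predicted unit scores the maximally wrong distance
    |T|, so it fails every threshold but still enters the mean."""
    by_id: Dict[str, Prediction] = {p.read_id: p for p in predictions}
    rows: List[dict] = []
    for read_id, truth in truths.items():
        pred = by_id.get(read_id)
        if pred is None or pred.unit is None:
            dist: int = len(truth)
            plen: Optional[int] = None
        else:
            dist = rotation_aware_edit(pred.unit, truth)
            plen = pred.unit_length
        rows.append(
            {
                "read_id": read_id,
                "true_unit_length": len(truth),
                "predicted_unit_length": plen,
                "rotation_distance": dist,
            }
        )
    return pd.DataFrame(rows)
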