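"""Reading input sequences and writing repeat predictions.

Input is FASTA or FASTQ (optionally gzipped), one prediction per record.
Output is a pair of files: ``<prefix>.units.fasta`` holding the inferred
repeat units and ``<prefix>.summary.tsv`` with one row per input read.
All user-facing coordinates are 1-based inclusive.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional

from Bio import SeqIO

__all__ = ["Read", "Prediction", "read_sequences", "write_predictions"]

# anything outside the 4-letter alphabet becomes the wildcard N
_CLEAN_TABLE = str.maketrans(
    {c: ("N" if c not in "ACGTN" else c) for c in map(chr, range(128))}
)

SUMMARY_COLUMNS = (
    "read_id",
    "unit",
    "unit_length",
    "region_start",
    "region_end",
    "copy_estimate",
    "tiled_edit_distance",
    "provenance",
)


@dataclass(frozen=True)
class Read:
    """A nucleotide sequence over {A,C,G,T,N} with a unique identifier."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Prediction:
    """The repeat call for one read.

    ``unit`` is ``None`` exactly when no repeat was found, in which case
    ``unit_length`` is 0 and ``provenance`` is ``"none"``.
    """

    read_id: str
    unit: Optional[str] = None
    unit_length: int = 0
    region_start: Optional[int] = None
    region_end: Optional[int] = None
    copy_estimate: int = 0
    tiled_edit_distance: int = 0
    provenance: str = "none"

    def __post_init__(self) -> None:
        has_unit = self.unit is not None
        if has_unit != (self.unit_length > 0) or has_unit != (self.provenance != "none"):
            raise ValueError(
                "unit must be absent exactly when unit_length == 0 and provenance == 'none'"
            )
        if self.region_start is not None and self.region_end is not None:
            if self.region_start > self.region_end:
                raise ValueError("region_start must not exceed region_end")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _clean(seq: str) -> str:
    return seq.upper().translate(_CLEAN_TABLE)


def read_sequences(path, format: str = "auto") -> List[Read]:
    """Parse FASTA/FASTQ into :class:`Read` records, in file order.

    ``format="auto"`` sniffs the first non-blank character ('>' FASTA,
    '@' FASTQ). Qualities are discarded, lowercase is folded to uppercase,
    and characters outside {A,C,G,T} are mapped to N. An empty file yields
    an empty list; malformed records raise ``ValueError`` naming the record
    index; duplicate ids are rejected.
    """
    path = Path(path)
    with _open_text(path) as handle:
        text = handle.read()
    stripped = text.lstrip()
    if not stripped:
        return []
    if format == "auto":
        first = stripped[0]
        if first == ">":
            format = "fasta"
        elif first == "@":
            format = "fastq"
        else:
            raise ValueError(f"cannot infer format of {path}: starts with {first!r}")
    elif format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")

    reads: List[Read] = []
    seen = set()
    parser = SeqIO.parse(io.StringIO(text), format)
    index = 0
    while True:
        try:
            record = next(parser)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(f"malformed {format} record {index} in {path}: {exc}") from exc
        seq = _clean(str(record.seq))
        if not seq:
            raise ValueError(f"malformed {format} record {index} in {path}: empty sequence")
        if record.id in seen:
            raise ValueError(f"duplicate read id {record.id!r} at record {index} in {path}")
        seen.add(record.id)
        reads.append(Read(record.id, seq))
        index += 1
    return reads


def write_predictions(predictions: Iterable[Prediction], out_prefix) -> None:
    """Write ``<prefix>.units.fasta`` and ``<prefix>.summary.tsv``.

    The FASTA holds one record per prediction that carries a unit, with the
    unit length, region coordinates, copy estimate and provenance in the
    description. The TSV has one row per input read, including no-repeat
    rows with empty unit fields.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    preds = list(predictions)
    with open(f"{out_prefix}.units.fasta", "w") as fa:
        for p in preds:
            if p.unit is None:
                continue
            fa.write(
                f">{p.read_id} length={p.unit_length} "
                f"region={p.region_start}-{p.region_end} "
                f"copies={p.copy_estimate} provenance={p.provenance}\n"
            )
            for i in range(0, len(p.unit), 80):
                fa.write(p.unit[i : i + 80] + "\n")
    with open(f"{out_prefix}.summary.tsv", "w") as tsv:
        tsv.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for p in preds:
            row = (
                p.read_id,
                p.unit or "",
                str(p.unit_length),
                "" if p.region_start is None else str(p.region_start),
                "" if p.region_end is None else str(p.region_end),
                str(p.copy_estimate),
                str(p.tiled_edit_distance),
                p.provenance,
            )
            tsv.write("\t".join(row) + "\n")
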