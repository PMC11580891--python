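"""Synthetic tandem-repeat reads with controlled error structure.

Three generators mirror the benchmark protocols the detector is built for:

* random units: a uniform random unit of a given length, concatenated a
  given number of times, with per-position errors injected into the repeat
  region and uniform random flanks (each as long as the error-free repeat
  region) attached on both sides;
* recurring-k-mer units: as above, except the unit itself starts with a
  random k-mer repeated 2 or 3 times (the rest of the unit is random),
  which makes within-unit periodicity compete with across-unit periodicity;
* composition from provided units: a higher-order pattern built by
  concatenating a given ordered list of unit sequences (e.g. ~171 bp
  alpha-satellite monomers), optionally flanked, with errors injected over
  the whole pattern.

The error model is per-position independent Bernoulli(rate): at most one
event per input position, equiprobably a substitution to a different base,
a deletion, or an insertion of a uniform base before the position. All
randomness flows through numpy's PCG64 generator, so records are fully
reproducible from integer seeds across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .sequence_io import Read

__all__ = [
    "Recurring",
    "SimConfig",
    "SimRecord",
    "random_dna",
    "inject_errors",
    "simulate_tandem_read",
    "simulate_recurring_kmer_read",
    "compose_from_units",
    "simulate_dataset",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class Recurring:
    """Recurring-k-mer structure of a unit: the k-mer length and how many
    times it is concatenated at the start of the unit (2 or 3)."""

    k: int
    kmer_copies: int

    def __post_init__(self) -> None:
        if self.kmer_copies not in (2, 3):
            raise ValueError("kmer_copies must be 2 or 3")
        if self.k < 1:
            raise ValueError("k must be positive")


@dataclass(frozen=True)
class SimConfig:
    unit_length: int
    copies: int
    error_rate: float = 0.0
    flanks: bool = True
    recurring: Optional[Recurring] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.unit_length < 1 or self.copies < 1:
            raise ValueError("unit_length and copies must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.recurring is not None:
            if self.recurring.k * self.recurring.kmer_copies > self.unit_length:
                raise ValueError("recurring k-mer copies must fit within the unit")


@dataclass(frozen=True)
class SimRecord:
    """A simulated read with its ground truth: the unit it was built from
    and the 1-based span of the (mutated) repeat region on the read."""

    read: Read
    true_unit: str
    region_start: int
    region_end: int


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-position errors: with probability ``rate`` a position suffers,
    equiprobably, a substitution to one of the three other bases, a
    deletion, or an insertion of a uniform base before it."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return seq
    out: List[str] = []
    for ch in seq:
        if rng.random() < rate:
            event = int(rng.integers(0, 3))
            if event == 0:  # substitution
                others = _BASES.replace(ch, "") if ch in _BASES else _BASES
                out.append(others[int(rng.integers(0, len(others)))])
            elif event == 1:  # deletion
                continue
            else:  # insertion before the position
                out.append(_BASES[int(rng.integers(0, 4))])
                out.append(ch)
        else:
            out.append(ch)
    return "".join(out)


def _build_unit(config: SimConfig, rng: np.random.Generator) -> str:
    if config.recurring is None:
        return random_dna(rng, config.unit_length)
    rec = config.recurring
    kmer = random_dna(rng, rec.k)
    tail = random_dna(rng, config.unit_length - rec.k * rec.kmer_copies)
    return kmer * rec.kmer_copies + tail


def _simulate(config: SimConfig, rng: np.random.Generator, read_id: str) -> SimRecord:
    unit = _build_unit(config, rng)
    clean = unit * config.copies
    mutated = inject_errors(clean, config.error_rate, rng)
    if config.flanks:
        left = random_dna(rng, len(clean))
        right = random_dna(rng, len(clean))
    else:
        left = right = ""
    seq = left + mutated + right
    return SimRecord(
        read=Read(read_id, seq),
        true_unit=unit,
        region_start=len(left) + 1,
        region_end=len(left) + len(mutated),
    )


def simulate_tandem_read(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    read_id: str = "sim",
) -> SimRecord:
    """One random-unit tandem read (``config.recurring`` must be absent).

    Draw order is fixed (unit, errors, left flank, right flank), so equal
    seeds give identical records. Errors go only into the repeat region;
    flanks are error-free and each as long as the pre-error repeat region.
    """
    if config.recurring is not None:
        raise ValueError("use simulate_recurring_kmer_read for recurring configs")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _simulate(config, rng, read_id)


def simulate_recurring_kmer_read(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    read_id: str = "sim",
) -> SimRecord:
    """One tandem read whose unit contains a recurring k-mer prefix."""
    if config.recurring is None:
        raise ValueError("config.recurring is required")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _simulate(config, rng, read_id)


def compose_from_units(
    units: Sequence[str],
    flank: str,
    error_rate: float,
    rng: np.random.Generator,
    read_id: str = "composed",
) -> Read:
    """Concatenate the given units in order into a pattern x; ``flank="axa"``
    attaches random flanks of length |x| on both sides. Errors are injected
    over the entire resulting string."""
    if not units:
        raise ValueError("at least one unit is required")
    if flank not in ("x", "axa"):
        raise ValueError("flank must be 'x' or 'axa'")
    x = "".join(units)
    if flank == "axa":
        x = random_dna(rng, len(x)) + x + random_dna(rng, len(x))
    return Read(read_id, inject_errors(x, error_rate, rng))


def simulate_dataset(config: SimConfig, n: int, seed: int) -> List[SimRecord]:
    """``n`` independent records under one setting; instance i is driven by
    the i-th child of ``SeedSequence(seed)``, so the collection is
    reproducible and instances are statistically independent."""
    children = np.random.SeedSequence(seed).spawn(n)
    sim = simulate_recurring_kmer_read if config.recurring else simulate_tandem_read
    return [
        sim(config, rng=np.random.default_rng(child), read_id=f"sim{idx}")
        for idx, child in enumerate(children)
    ]
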