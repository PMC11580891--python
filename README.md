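# equirep

Tandem repeat detection in error-prone long reads.

A tandem repeat is a stretch of DNA made of contiguous, near-identical
copies of a *unit* — from short microsatellites to ~171 bp alpha-satellite
monomers and the concatemers produced by rolling-circle amplification
(RCA) sequencing of circular templates. Reconstructing the unit from a
single noisy long read is hard precisely where it matters most: long units,
few copies, 10–20% error rates. `equirep` is a detector built for that
regime, together with the simulator used to benchmark it and
rotation-aware evaluation utilities.

## Method

Given a read R, detection runs in four steps.

1. **Region.** Exact k-mer matches (default k = 9) are chained into the
   best colinear chain, whose padded span is the candidate substring R′.
   A *diagonal-free self local alignment* — Smith–Waterman of R′ against
   itself restricted to the strict upper triangle of the table, so a
   position can never align to itself — confirms the repeat: with m tandem
   copies the optimal off-diagonal path aligns copy r to copy r+1, and its
   footprint trims R′ to the repeat region S.
2. **Equivalence classes.** Positions i ~ j of S are *equivalent* when they
   descend from the same unit position. Every significant traceback path of
   the self-alignment table votes for the pairs it aligns: path scores are
   accumulated into a sparse symmetric matrix M over position pairs. M is
   refined for 5 rounds — any triple (i, j, k) whose three pairwise entries
   are all positive reinforces itself by their minimum, followed by
   row-mass normalization — and non-overlapping high-mass paths of the
   refined matrix are merged into equivalence classes 𝒞 with a union-find
   (no class may contain two positions closer than 5 bp). Each class gets a
   majority-vote representative letter.
3. **Candidates.** A weighted directed graph on 𝒞 counts how often a
   member of class A is followed (directly, or across a single inserted
   base) by a member of class B. Walking one unit of the repeat is a cycle
   in this graph, so the unit is spelled from the cycle with maximal
   bottleneck (minimum edge weight) among cycles covering more than half
   of S. Over-combined classes are split against their strongest in-edge
   for up to 5 rounds (one candidate per round), and for units of 2–6 bp
   the most frequent k-mer under rotation is proposed directly — up to 11
   candidates in total.
4. **Selection.** Each candidate is tiled to |S| and the one with the
   lowest edit distance to S wins.

See `docs/methods.md` for parameter semantics, numerical choices, and
limitations.

## Worked example

```python
import equirep as eq

# a 50 bp unit, 8 copies, 10% errors, flanked by random sequence
rec = eq.simulate_tandem_read(
    eq.SimConfig(unit_length=50, copies=8, error_rate=0.10, seed=3)
)
pred = eq.detect_read(rec.read)
print(pred.unit_length, pred.copy_estimate, pred.provenance)
print(pred.region_start, pred.region_end, pred.tiled_edit_distance)
print(eq.rotation_aware_edit(pred.unit, rec.true_unit))
```

prints

```
50 8 graph
395 806 40
0
```

The 1200 bp read (true repeat region 401–800) is trimmed to 395–806; the
bottleneck cycle spells a 50 bp unit estimated at 8 copies, whose tiling
matches the noisy region at edit distance 40 (the injected errors), and
which equals the true unit exactly up to rotation (distance 0).

The same pipeline from the shell:

```sh
equirep simulate --unit-length 50 --copies 8 --error-rate 0.1 --n 4 \
    --seed 3 --out sim.fa --truth truth.tsv
equirep detect --input sim.fa --output pred
equirep evaluate --pred pred.units.fasta --truth truth.tsv --out metrics.tsv
# n=4 exact=4 lt10=4 lt20=4 mean=0.00
```

`detect` writes `pred.units.fasta` (one record per detected unit) and
`pred.summary.tsv` (one row per read, including no-repeat rows);
`evaluate` reports rotation-aware edit distances against the truth table
and the per-setting summary: exact matches, counts below 10% and 20% of
the unit length, and the mean distance.

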