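# Methods

## Problem and model

A read R is assumed to contain at most one tandem repeat region S: m
mutated copies of an unknown unit U, flanked by unrelated sequence. Errors
are point events (substitutions, insertions, deletions), as produced by
long-read sequencers. The goal is to reconstruct U (up to rotation — a
detector cannot know where the cycle "starts") and the span of S.

The central object is the equivalence relation on positions of S: i ~ j
when S[i] and S[j] descend from the same position of U. In the ideal
error-free case the relation's classes are exactly the |U| residue classes
of positions modulo |U|; errors blur the relation, and the detector's job
is to recover it from noisy alignment evidence before reading the unit off
the class structure.

## Pipeline and parameters

### Step 1 — region

Anchors are pairs of identical k-mers (`seed_k`, default 9 bp). At 10%
per-base error the probability that a 9-mer survives intact in two copies
is roughly 0.9^18 ≈ 0.15 — sparse but ample for coarse localization, since
a 200 bp unit offers ~190 anchor sites per copy pair. Anchors are chained
by dynamic programming (score = anchors in the chain minus one point per
50 bp of offset discontinuity, discontinuities over 100 bp disallowed);
the best chain's span, padded by 20% per side, is the candidate substring.
Chains shorter than `min_chain` = 3 anchors fall back to the whole read.
Two tractability guards keep the coarse stage linear-ish: k-mers occurring
more than 100 times yield no anchors, and predecessor search in the chain
DP is banded. Both only affect the coarse span, which the alignment stage
re-trims.

The diagonal-free self-alignment uses linear gaps with `match` = +2,
`mismatch` = −3, `gap` = −4. The two absolute thresholds downstream
(path score 25, acceptance length 20) are meaningful only relative to a
concrete scale; with match = +2 a clean 13-column match (score 26) clears
the path threshold. All three scores are CLI-tunable. N never matches
anything, including itself.

**Region acceptance.** The optimal path aligns a segment [a..b] of S to a
later segment [c..d]; the region is S = [a, d], covering both copies the
alignment touches. The path is accepted when the total number of residues
it covers, (b−a+1) + (d−c+1), reaches `min_align_len` = 20. For m
error-free copies of U this measure equals 2(m−1)|U|, so the default
admits three copies of a 7-mer (28 ≥ 20) while two isolated 4-mer copies
(16) are rejected. Counting residues on both segments, rather than
alignment columns, is the package's reading of "alignment length"; it is
the choice under which the detector's own recovery guarantee (units ≥ 7 bp
at ≥ 3 copies, error-free) is tight. Additionally, a region whose optimal
alignment score falls below `min_path_score` is rejected outright: such a
region provably yields an empty evidence matrix in Step 2, so it carries
no repeat evidence, and rejecting it is what keeps repeat-free reads from
receiving spurious short-unit calls.

### Step 2 — classes

Path endpoints are the positive cells of the table that are maximal in a
`window` × `window` box centered on them (default 7; plateau ties keep the
row-major-first cell so flat ridges are traced once). Endpoints are
processed by descending score; each traceback walks until it hits a cell
claimed by an earlier kept path, a zero cell, or the table border, and
scores the differential between its endpoint and termination cell. Paths
scoring below `min_path_score` = 25 are discarded as random matches.
Kept paths write their score to every cell they cover — gap cells
included — with collisions keeping the larger score (stronger evidence).
When detection trims a larger table to the region window, tracebacks
terminate at the window border and the border cell's score is absorbed
into the differential, so outside mass never leaks into the window.

Refinement runs `rounds` = 5 iterations. Deltas are read from the
round-start matrix and accumulated, exactly as stated by the update rule;
an entry participating in no triple is changed only by normalization.
Because the matrix is stored once per unordered pair, a literal row-wise
rescale M′[i,j] · A[i]/A′[i] would break symmetry; each entry is instead
scaled by the geometric mean √((A[i]/A′[i]) (A[j]/A′[j])) of its two row
factors, which preserves symmetry, reduces to the literal rule when the
factors agree, and conserves row mass exactly in the uniform case and
approximately otherwise.

Path extraction over the refined matrix is a DP over nonzero cells with
diagonal/vertical/horizontal predecessors; the best path is peeled, its
cells removed, and only affected scores recomputed, until the best
remaining path scores below 1. Class construction visits peeled cells by
descending refined weight and unions i with j unless the merged class
would contain two positions at distance ≤ `min_separation` = 5 (with ≤,
units of length 6 — the top of the k-mer heuristic's range — remain
mergeable). Majority letters break ties alphabetically; N never votes; an
all-N class is labeled N.

### Step 3 — candidates

Edge weights count direct successions plus successions across a singleton
class (a likely inserted base); the singleton condition is evaluated on
the current partition, including after splits. The bottleneck-cycle
search descends through the distinct edge weights; at each threshold the
subgraph keeps only edges at least that heavy, and the first threshold
admitting a simple cycle (length ≥ 2) covering more than half of S wins —
any covering cycle found there attains the optimal bottleneck, which makes
the descent equivalent to the binary search one would otherwise use.
Subgraphs with ≤ 20 nodes are searched exactly by cycle enumeration
(capped at 2·10⁵ cycles; overflow degrades to the heuristic); larger
subgraphs are searched by greedy maximum-weight walks from the 5 largest
classes until a node repeats. The coverage-constrained bottleneck cycle
problem is not polynomially solvable in general; exact-on-small keeps the
search oracle-checkable while the greedy walk handles the long-unit
graphs, where the consensus chain dominates the weights.

Splitting round r admits classes of size at least
θ_r = max(2·median − (r−1), median + 1), the median taken over all
classes including singletons; the admission size thus shrinks by one per
round but never reaches the median. Each admitted class is split against
its maximum-weight in-edge (ties: smaller class index) into followers B1
and the rest B2; empty sides skip the split. Fewer than 11 candidates is
normal (no qualifying cycle, short regions); selection operates on
whatever is present.

### Step 4 — selection

Candidates are tiled to exactly |S| (truncation, no phase search) and
scored by edit distance via edlib. Ties prefer the shorter unit — the
primitive period, since a doubled unit tiles equally well — then the
provenance order graph, split-1..5, kmer-2..6. The copy estimate is
|S|/|U| rounded half away from zero.

## Simulator

The generator reproduces the benchmark protocols the detector targets:
uniform random units of a given length, a given copy number, per-position
errors at a given rate injected into the repeat region only
(equiprobable substitution / deletion / insertion-before, at most one
event per input position), and uniform random flanks on both sides, each
as long as the *pre-error* repeat region. The recurring-k-mer variant
builds the unit as a random k-mer repeated 2 or 3 times plus random fill,
making within-unit periodicity compete with across-unit periodicity. The
composition generator concatenates a provided ordered list of units (the
higher-order-repeat scenario), optionally flanked, with errors over the
whole string. All draws come from numpy's PCG64 generator in a fixed
order, so records are bit-reproducible from integer seeds; datasets use
`SeedSequence.spawn` for independent per-instance streams.

What the simulator does *not* model: realistic long-read error profiles
(homopolymer-length biases, quality-correlated error bursts), multiple
repeat regions per read, nested or interrupted repeats, non-uniform base
composition. Passing tests on simulated data therefore demonstrate
robustness to dense uniform point errors, not to instrument-specific
artifacts.

## Evaluation

The headline metric is rotation-aware edit distance: the minimum edit
distance between the truth and any cyclic rotation of the prediction.
Summaries report exact matches and counts strictly below 10% and 20% of
the true unit length, plus the mean. A read with no predicted unit counts
as maximally wrong (distance |T|) so summaries stay total. For data
without ground-truth units the semi-edit distance (minimum edit distance
between the input and any substring of a tiling of the prediction, via
edlib's infix mode) is available.

## Validation scale

The test suite validates the alignment DP cell-by-cell against a naive
reference on strings up to 30 bp; the bottleneck search against exhaustive
cycle enumeration on 200 random digraphs of up to 8 nodes; the distance
measures against brute-force oracles on all binary strings up to length 8;
refinement against hand-computed fixtures to 1e-9; and the full pipeline
on simulated reads up to 200 bp units × 10 copies (reads of ~6 kb), 50
instances at 10% error — sizes at which the whole suite runs in about a
minute on one core.

## Known limitations

* One repeat region per read; the single best chain/alignment wins.
* Alignment scoring is heuristic; the published thresholds (20, 25) are
  calibrated to the default scores and should be revisited if the scores
  are changed.
* Refinement models substitution noise; insertions and deletions are
  handled downstream (singleton-bridged edges, class splitting) rather
  than inside the refinement operator.
* The greedy cycle walk on large class graphs is a heuristic; it can miss
  the optimal covering cycle on adversarial graphs, though the splitting
  and k-mer candidates plus distance-based selection buffer such misses.
* Very short units (< 7 bp) at very low copy number sit below the region
  acceptance threshold by construction.
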