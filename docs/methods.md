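# Methods

## Data model and coordinate conventions

All coordinates are 1-based inclusive `[α, β]`; the binary indicator is
defined pointwise as `h_{γ,x} = 1` iff `α_k ≤ x ≤ β_k` for some retained
peak `k`. BED-family I/O (narrowPeak, reads BED, ChromHMM segmentations,
track export) converts to/from 0-based half-open at the file boundary, and
the conversion is an involution. Two length notions coexist deliberately:
the *width* statistic of a peak is `β − α` (the conventional summary printed
for called peaks), while all coverage and distance arithmetic uses the
inclusive span `β − α + 1`, since the indicator is pointwise. Abutting
intervals `[a,b], [b+1,c]` are merged, so a `BinaryTrack` is a canonical
representation of its indicator; this makes track equality, idempotence of
re-unioning, and the sweep algorithms well-defined.

The ranking score is the caller's `−log10 p` (narrowPeak column 8), kept on
the log scale throughout — example peaks have p-values like 10^−422, far
below float underflow. Ties in score are broken by genomic coordinate
(layout chromosome order, then start, then end) so rankings are
deterministic across platforms; the choice is ours, as callers do not
specify one.

## Hamming distance by interval sweep

`H(a, b) = covered(a) + covered(b) − 2·covered(a ∩ b)`, with the
intersection length from an endpoint sweep over the two sorted disjoint
interval lists (positions of depth 2). This is exactly the pointwise
symmetric-difference count — an oracle test compares it against explicit
0/1-vector XOR counting on hundreds of random track pairs — but runs in
O((n+m) log(n+m)) in the number of intervals instead of O(genome length).
Distances are exact integers (bp); no floating point enters before linkage.
Adding a sample to a cohort of N reuses the cached N×N block and computes
only N new distances. The Dice dissimilarity `1 − 2|a∩b|/(|a|+|b|)` is a
drop-in alternative metric; it is undefined when both tracks are empty.

## Linkage and the Ward height convention

Agglomeration repeatedly merges the active pair with minimal set distance.
The UPGMA set distance is the mean pairwise sample distance; the Ward set
distance is defined through the quantity

    Q(C₁,C₂) = D₁₂/(n₁+n₂) − n₂D₁/(n₁(n₁+n₂)) − n₁D₂/(n₂(n₁+n₂)),

which has squared-distance units (for singletons Q = d²/2). We report
heights as `sqrt(max(Q, 0))` so that the singleton identity
`H_Ward({a},{b}) = d/√2` holds in distance units; the raw Q is retained in
every merge record. Because `sqrt` is strictly increasing, merge order —
and therefore every penalty value — is identical under either convention.
Under this convention our Ward heights equal scipy's `linkage(..., 'ward')`
heights divided by √2, which the test suite uses as an independent
cross-check; UPGMA/WPGMA/centroid/median heights match scipy's directly.

The default implementation updates distances with Lance–Williams
recurrences (Ward and the centroid methods operate on the squared
quantity); a `direct=True` path re-evaluates the set formulas from the
original matrix at every step and is verified to agree with the fast path
to 1e−10 on random instances. Minimum ties are broken by the
lexicographically smallest historical index pair `(τ′, τ″)` — the
uniqueness assumption of the textbook algorithm is replaced by a total,
deterministic rule. A merged cluster's member order is the first operand's
order followed by the second's; the root's member order is the drawn leaf
ordering, leaves sit at `(position, 0)` and an internal node at the midpoint
of its children's x at its merge height.

## Penalty

`τ(ν)` is found by scanning the 2N_s − 1 historical clusters in creation
order for the first containing S_ν; existence is guaranteed by the root.
`λ_ν = |C_τ(ν)| − |S_ν|`, `λ = Σ λ_ν`, with `0 ≤ λ ≤ (|T|−1)·|S|`. Empty
types (possible when an explicit type universe is declared) contribute 0.
λ depends only on merge topology/order, never on heights — asserted by a
monotone-transform invariance test.

## Parameter selection

Grid search evaluates λ at every `(M_cut, p_G)`; per-sample rankings are
supplied per `p_G` (peak calling is by far the dominant cost and happens
once per threshold). At real-data scale the natural grid is an `M_cut`
step of 2000 and `1.5 ≤ −log10 p_G ≤ 4`; the test fixtures use
proportionally smaller grids. Among thresholds attaining the global
minimum, the `p_G` with the longest contiguous minimizing `M_cut` run is
chosen (first in grid order on ties) and the plateau midpoint reported: the
lower median of the run, the longest run first on ties when minimizers are
non-contiguous. `plateau_midpoint` infers grid contiguity from the smallest
gap between minimizers unless an explicit `step` is given, since it
receives only the minimizing values.

## Robustness to read loss

`downsample_reads` removes exactly `⌈r·N_r⌉` reads uniformly without
replacement (seeded, bit-reproducible; survivors keep input order).
`robustness_curve` downsamples every sample simultaneously at each
(r, replicate), re-calls peaks through any callable satisfying the caller
contract, and re-runs the pipeline at fixed `(M_cut, p_G)`; `r = 0`
involves no randomness and reproduces the baseline λ exactly. Per-sample
downsampling (one sample at a time) would be the alternative reading of the
protocol; we chose simultaneous loss as the more realistic depth-loss model
and keep per-sample seeds so either accounting can be reconstructed.
Downsampling applies to the analysis-ready (deduplicated, MQ-filtered) read
set; upstream preprocessing is a documented prerequisite, not implemented.

## Classification

`H_Ward({ζ}, S_ν)` needs only the distances between ζ and the members of
each type plus the cached within-type distances (D₁ = 0 for a singleton
query), so classifying a query against an N-sample reference costs N
Hamming distances. Queries are processed independently and never enter the
reference set. Type ties are broken alphabetically. The √ height
convention cannot change a ranking (strictly increasing transform).

## Annotation profiles

Peaks are grouped into rank windows of 1000 (window j covering ranks
1 + (j−1)·1000 …); a peak belongs to state y iff its center satisfies
`σ ≤ (α+β)/2 ≤ ε` for some state interval, tested exactly on integers as
`2σ ≤ α+β ≤ 2ε` so half-integer centers need no rounding rule. Fractions
always use the window size as denominator. Windows extending past the
available peaks are dropped. Within one state, intervals must be disjoint;
states may in principle overlap each other, in which case per-window
fractions can sum above 1 (a tiling segmentation sums to ≤ 1, with equality
when every center is covered).

## Synthetic cohorts: what they emulate, and what a green test shows

The generator states a world in which cell-type identity is carried by a
fixed archetype of high-significance peaks: 3 types × 4 samples on a
2 × 100 kb toy genome, 300 informative peaks per type of width 40–80 bp
(one third shared across all types, modelling overlap between related cell
types), per-sample positional jitter of sd 5 bp, and 200 per-sample uniform
noise peaks. Informative scores (uniform on [20, 300) in −log10 p units)
exceed noise scores ([2, 10)) by a fixed margin, which encodes the
assumption that biologically reproducible peaks out-rank
experiment-dependent ones — the very assumption that makes rank truncation
a sensible normalization. Archetype scores are drawn once per type, so
every sample of a type retains the same peak subset at any cutoff and the
penalty landscape has a clean plateau. Sample sizes and the toy genome are
chosen for desk-scale determinism; noise density and jitter are stated
once, not tuned.

Consequently a green pipeline test establishes internal correctness —
exact interval arithmetic, linkage equivalences, penalty accounting,
recovery of a planted margin — but not performance on real cohorts, where
informative and noise scores interleave, peak widths correlate with rank,
and type archetypes are not literally shared blocks. The toy pileup peak
caller (maximal runs of coverage ≥ threshold; score = calling floor + max
pileup) exists so the caller contract and robustness paths run hermetically;
it makes no claim of MACS2 fidelity. Real-cohort headline numbers therefore
require real data and the external caller and are out of scope for the test
suite.

## Numerical and degenerate-input choices

Ward's Q is clipped at 0 before the square root (it can be a few ulps
negative for coincident samples). Distance matrices must be exactly
symmetric with a zero diagonal; construction validates this. An empty
minimizer set, a non-increasing M_cut grid, overlapping cluster arguments,
r outside [0, 1], both-empty Dice inputs, and peaks outside the genome
layout raise immediately with specific messages. The external-caller
wrapper requires the executable on PATH and leaves no partial output behind
on failure; its flag construction and error paths are tested against a stub
executable.

## Known limitations

- Peak calling itself is wrapped, not implemented; results inherit the
  caller's modelling choices.
- The penalty scan over historical clusters is O(N_s²) per type — trivial
  at cohort scale (N_s ≲ 10³) but not tuned beyond that.
- `plateau_midpoint` cannot distinguish a genuinely sparse plateau from a
  coarse grid without an explicit `step`.
- WPGMA/UPGMC/WPGMC have no direct-formula oracle in-package (their set
  formulas are textbook material); they are validated against scipy only.
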