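# Methods

## Model

wMEC (weighted Minimum Error Correction): given an n×m fragment matrix
over {0, 1, −} with positive per-call weights, find a bipartition of the
reads into two sets and a minimum-total-weight set of allele flips making
both sets conflict-free. Weights are taken as given input; they are
understood as combined base-call/mapping confidences, but no combination
formula is imposed — the simulator offers a phred conversion
(round(−10·log₁₀ error_rate)) and a fixed mode, nothing more.

The solver is an exact column dynamic program over bipartitions of the
*span-active* reads at each column, with the per-column recurrence and
compatibility transfer described in the README. Its complexity is
O(Σ_j 2^{c_j}) time and O(2^{max c_j}) space, i.e. fixed-parameter
tractable in coverage.

## Span activity and gaps

A read is active at every column between its first and last call,
inclusive. A paired-end fragment with an internal call-free gap therefore
stays in the state space across the gap, contributing zero local cost
there. This is deliberate: the compatibility transfer only constrains
reads active in *consecutive* columns, so call-based activity would let a
gapped read silently change parts across its own gap and return
inconsistent assignments. The cost optimum is unaffected for gapless
reads; for gapped reads span activity is what makes the returned
`read_part` well defined. A consequence is that coverage (and hence DP
work) counts spans, not calls.

## Modes

* **default** — each part independently takes its cheaper consensus
  allele per column; a site whose column is non-monotone may legitimately
  come out homozygous, and a part with no call at a column emits '−'.
* **all-het** — the two parts are forced to complementary alleles
  (min{W¹_R + W⁰_S, W⁰_R + W¹_S} per column); a part with no call takes
  the complement of the other part's allele. The all-het optimum is ≥ the
  default optimum on every instance, being a constrained minimum.

On error-free simulated data (which is heterozygous at every site by
construction) the all-het optimum is 0 and the recovered haplotypes equal
the truth per block up to pair swap. In default mode the optimum is also
0, but cost-0 solutions may mix reads of both haplotypes in one part when
they never share a call column; this shows up as homozygous site calls,
not as switch errors.

## Determinism and tie-breaking

Wherever the optimum is non-unique the engine picks the numerically
smallest bipartition mask: within a column table, per projection key, at
the final column, and in the map-reduce merge. Consensus-allele ties go to
allele 0 (default mode) and to the R=0/S=1 orientation (all-het). This is
stricter than required — runs with different schedules may in principle
return different cost-equivalent optima — and is what makes sequential,
chunked, and multi-worker execution byte-identical, which the test suite
asserts. Exactness of the equalities assumes integer (or integer-valued)
weights, which all fixtures and the simulator use; with arbitrary floats
the chunk entry-point re-initialisation can differ from the incremental
sum by rounding.

## Symmetry halving

Swapping R and S leaves every cost invariant, so enumerating the masks
that fix one read's part halves the work to Σ_j 2^{c_j −1} (the classic
m·2^{cov−1} bound). We fix the *highest*-indexed active read to part R,
so the halved space is exactly the contiguous Gray-rank range
[0, 2^{c−1}) and chunking applies unchanged; fixing the lowest-indexed
read would scatter the kept masks through rank space. Projection tables
fold each mask's complement back in, so boundary keys involving the fixed
read stay reachable and full- and half-enumeration produce identical
results (asserted in the suite).

## Parallel contract

A column at or above the coverage threshold is split into contiguous
Gray-rank chunks of `chunksize` (default 4096) ranks. Each chunk
initialises its four part sums from scratch at its entry mask (the Gray
code of the chunk's first rank — e.g. rank 4 of a 3-bit space enters at
110) and proceeds incrementally; it records per-boundary-key minima in a
private table. A sequential reduce merges the private tables with the
smallest-mask tie rule, making the merged projection a pure function of
the inputs, independent of worker count and scheduling. Workers are
plain threads; the per-chunk arithmetic is identical to the sequential
path, so results match byte for byte. The threshold default of 20
reflects where a column's 2^c table is large enough for task overhead to
amortise; below it the sequential path runs and no tasks are spawned.
Only the algebraic contract is in scope here — no lock-free queues,
pinning, or distributed execution.

## Hard coverage limit

A column of coverage c needs a 2^c-entry float table; the default refusal
limit of 25 (2^25 ≈ 33M entries, ~256 MiB) errs toward refusing rather
than thrashing. The intended route for deeper data is
`prune_to_max_coverage`: scan columns left to right and, at an
over-covered column, greedily drop the active read with the smallest
total call weight (ties: fewest calls, then highest fragment index). The
rule is a heuristic of this package's own design and is fully
deterministic; the `seed` parameter exists for interface stability and is
unused. Pruning can only lower the optimum (fewer reads, fewer
constraints), which the suite checks against the exhaustive oracle.

## Simulator

The generator emulates an all-heterozygous benchmark design in SNP-column
space: h1 uniform random bits, h2 its complement; reads drawn with
geometric lengths (mean `read_len` = 6 columns), uniform starts over
positions where the span fits, fair-coin source haplotype, independent
per-call flips at `error_rate`, and phred or fixed weights. Paired ends
are one fragment with a geometric call-free gap (mean `mean_gap` = 2).
The read count is m·coverage/E[span], so realised mean coverage tracks
the target. Defaults (coverage 15, error rates 0.01/0.05 in the tests)
mirror the coverage tiers (15×/20×/25×) and substitution rates (1 %/5 %)
of long-read benchmark designs. One `numpy` generator seeded once drives
everything, in a fixed order per read: length (and gap), start, source,
then one error draw per column.

What the simulator does *not* model: base-level sequence, indels, mapping
artifacts, non-uniform error profiles, or genotype errors (every site is
truly heterozygous). Passing tests therefore demonstrate correctness of
the optimizer and its contracts, not calibrated accuracy on real
sequencing data. Indel processes affect base alignment upstream of the
SNP matrix and have no SNP-space analogue here, so they are omitted.

## Evaluation

Because the informal notion of "error rate" is ambiguous, the scorer
reports both standard quantities explicitly, pooled over blocks:

* **switch error rate** — among consecutive phased heterozygous sites of
  a block, the fraction of adjacent pairs whose relative phase disagrees
  with the truth;
* **site error rate** — phased sites whose allele pair mismatches the
  truth under the best per-block orientation;
* **phased fraction** — phased sites over phasable sites, where every
  block column (coverage ≥ 1) is phasable and a site is phased when both
  haplotypes carry a definite allele.

Both error metrics are invariant under a global haplotype-pair swap since
each block is scored under its own best orientation.

## Problem sizes in the test suite

Oracle-equivalence runs use 200 random matrices with n ≤ 8, m ≤ 6 and
integer weights 1–10 per mode — small enough for the 2^n exhaustive
oracle while covering gapped reads, multi-block layouts and ties. The
end-to-end recovery check uses m = 200 at 10× over 20 seeds, pruned to
maximum coverage 15 before phasing — the same cap-then-phase pipeline the
CLI exposes (`--max-coverage`), and the standard way to bound the
exponential state space on real data. The trend check (switch error
non-increasing from 15× to 25×) is a monotonicity property over seeds,
not a comparison against any published figure.

## Known limitations

* Exact DP memory grows as 2^coverage; there is no disk-backed or
  compressed table mode, so data deeper than the hard limit must be
  pruned.
* Read pruning is greedy, not optimal read selection.
* BAM/CRAM and input-VCF ingestion are out of scope; the fragment dialect
  is the only input format. VCF is emitted with placeholder REF/ALT
  alleles (the matrix abstracts nucleotides away).
* The brute-force oracle is capped at n = 15 reads by design.
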