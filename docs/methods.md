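# Methods

This note records the model and procedure `multichip` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## Allocation model

A read with k candidate alignments (all hits with ≤ 2 mismatches; reads
with ≥ 100 hits discarded) is represented by its leftmost alignment
coordinates p_1 … p_k; strand is deliberately ignored at this stage so that
forward and reverse tags of one binding event reinforce each other.  The
fractional count field c(·) assigns each genomic position the summed
weights of alignments starting there.  Iteration t+1 sets

    f_i  =  N(p_i, w) / Σ_j N(p_j, w),     N(p, w) = Σ_{|q − p| ≤ w} c_t(q)

with the uniform fallback 1/k if every window sum is zero.  Updates are
synchronous: all reads are rescored against the complete count field of
iteration t before any weight changes.  Uni-reads stay at weight 1 and act
as anchors; the procedure is an iterated "rescue" and a heuristic cousin of
the EM estimators used for transcript abundance.

Parameters, defaults, and rationale:

* `window_halfwidth` w = 100 bp.  The window [p − w, p + w] must satisfy
  2w ≤ L (fragment length) so that uni- and multi-reads in one bin describe
  the same binding event; exceeding this warns rather than errors.  25 and
  50 bp are equally valid choices; 100 is the largest value compatible with
  L = 200 and is configurable.
* `n_iterations` = 200, fixed, no early stopping by default (an optional
  convergence tolerance on the maximum weight change is off by default).
* Initialization is the uniform 1/k, making the first reallocation
  equivalent to starting from a flat count field away from boundaries.
* The read's own previous-iteration fraction is included in its window
  sums; nothing in the update excludes self-counts, and including them
  makes the zero-mass degenerate case unreachable in normal operation.

Verifiable consequences used as oracles: per-read weights sum to 1 after
every iteration; a multi-read with two identical neighborhoods stays at
0.5/0.5 indefinitely; a candidate sitting next to a single uni-read (with
the alternative candidate isolated) follows the closed-form recursion
f′ = (1 + f)/2, reaching 1 − 2⁻¹¹ after 10 iterations; and allocation is
invariant to read order.

### Count index

Counts are stored sparsely — only positions where at least one alignment
starts — in a Fenwick (binary indexed) tree per chromosome with O(log n)
point updates and interval sums (`CountIndex`).  The default allocation
engine replaces per-query tree traversals with one prefix-sum array per
iteration over the same compressed positions; both engines implement the
same arithmetic and agree to 1e-12 on identical inputs (exactly, on
integer-valued counts).  The Fenwick path is retained both as the
structure of record and as an independent cross-check.

## Mappability and GC

n(x) counts occurrences of the k-mer starting at x over both strands of
the whole genome (k-mers containing N get the sentinel 0).  Def 1 scores
1 iff n(x) = 1; Def 2 scores 1/n(x) for n(x) < 100 and 0 otherwise, the
cap mirroring the ≥ 100-hit read filter.  Because counts at a position x
arise, after fragment extension, from forward tags starting in
[x − L + 1, x] and reverse tags whose 5′ ends lie in [x, x + L − 1] (the
reverse-strand score of a 5′ end y equals the forward score at y − k + 1
under both-strand counting), the extended score averages the per-start
scores over those 2L contributing starts.  The exact normalizing constants
of the published extension formulas are not recoverable from the available
text; this implementation divides by the number of in-genome contributing
starts, which preserves the [0, 1] range and truncates cleanly at
chromosome ends.  Bin-level mappability and GC are plain per-bin means;
bins consisting solely of N are excluded everywhere.

## Binning

Each weighted alignment is extended strand-aware to L (forward
[start, start + L), reverse [end − L, end), clipped at chromosome
boundaries) and adds its weight to every bin its fragment overlaps — the
literal "reads overlapping each bin" reading rather than midpoint
assignment.  Bin size defaults to 200 bp to match L, within the 50–250 bp
working range.  Fractional totals are rounded half-away-from-zero by
default; ceiling and floor give the upper/lower count bounds and produce
nearly identical peak sets (pairwise Jaccard ≥ 0.9 on the benchmark).
Fractional sums are pre-rounded at 9 decimals so accumulation noise cannot
flip a ceiling/floor.  Strand matters for binning even though allocation
ignored it: allocation's strand-blindness is purely the leftmost-start
counting convention.

## Peak calling

**Conditional binomial.**  Under independence of ChIP (X) and input (Y)
counts in an unbound bin, X | X + Y ~ Binomial(X + Y, p0).  p0 is the ChIP
share of counts among bins with X + Y ≤ 1 (threshold configurable); when
no such bins exist — common at desk-scale depth — the global depth ratio is
used with a warning.  Upper-tail p-values are exact binomial tails;
multiple testing is Benjamini–Hochberg (the mechanism is not prescribed by
the source method; BH is the standard step-up choice).  The test is
conservative on discrete nulls, which the calibration test acknowledges by
bounding rather than matching the nominal level.

**NB mixture.**  Background ChIP counts follow a negative binomial with
log mean β₀ + β_M·M + s(GC) + β_Y·log(1 + Y), where s(·) is piecewise
linear with knots at the GC first and third quartiles, and dispersion α
estimated by Pearson moment matching.  Bound bins follow
shift + two-component NB mixture; the shift constant (default 3)
represents the minimum count observable in a bound region, and the signal
components initialize at 5× and 20× the mean background level.  Fitting
alternates (i) the background regression on bins currently assigned to the
background (responsibility < 0.5) with (ii) responsibility updates from
the full mixture; initialization is deterministic (Pearson residuals > 3
from an all-bins fit seed the bound class), so the fit needs no RNG.  The
published estimator's exact equations, per-chromosome fitting, and
BIC-selected tuning constants are simplifications here: one fit per
dataset, fixed shift.  FDR is controlled directly on posteriors: declare
the largest set of bins whose mean background posterior is at most the
level.  Simulation checks: the mappability coefficient is recovered within
a few percent at 50,000 bins, realized FDR stays below 1.5× nominal, and
with no bound bins the mixture proportion collapses below 0.01.

Both routes then drop bound bins with fewer than 30 ChIP tags (scaled
depth makes this attainable at desk scale) and merge contiguous bound bins
into peaks carrying summit, count sums, depth-scaled mean log2 enrichment
(pseudocount 1), and mean mappability/GC.

## Peak comparison and classification

A peak found by only one of the UR/MR analyses is "only" if the other
sample's read count over its span is below 20; non-overlapping peaks above
that support are "ambiguous" rather than forced into a class.  Reads map
to a peak when an alignment interval overlaps the peak region (not the
extended fragment); within-peak multiple mappings of one read collapse to
a single entry with summed weight.  The similarity between peaks i and j is

    s(i, j) = Σ_shared (1 − |w_ri − w_rj|),

normalized by the larger read count of the pair.  This is the unique form
consistent with three verbatim constraints of the source description
(self-similarity equals the read count; all-0.5 shared weights give the
overlap count; 0.9/0.1 weights make peaks more different than 0.6/0.4),
whose explicit formula is not recoverable from the available text.  Paired
t and Wilcoxon signed-rank tests on the shared weight pairs ask whether
shared multi-reads favor one peak.

MR-only peaks sharing no multi-reads are Type-III.  Otherwise criteria are
evaluated against the maximum-normalized-similarity partner (the partner is
ambiguous in the source when a peak shares reads with several peaks; the
max-similarity reading matches how similarity is reported there):
Type-II if (a) unshared multi-read mass ≥ 20, or (b) ≥ 20 uni-reads, or
(c) unshared/shared multi-read mass ratio ≥ 2; else Type-I, the
duplication-artifact signature.

Saturation draws one uniform variate per read so subsamples are nested by
construction; uni- and multi-pools are subsampled separately, the full
pipeline re-runs per fraction, and recovery is the percentage of gold
peaks (called on the full data) overlapped.

## Annotation, motifs, profiles

Location categories follow the precedence PromDup > Prom > GenicDup >
Genic > Dup > None.  The promoter half-width is ±2 kb by default — a
configurable choice, not a fact inherited from the source, whose window is
unrecoverable; genic windows span 10 kb upstream of the TSS to 1 kb
downstream of the TES.  A peak earns the "Dup" qualifier when the matched
gene or the peak itself overlaps a segmental duplication; with an empty
duplication set the categories collapse exactly (PromDup→Prom,
GenicDup→Genic, Dup→None).

Consensus motifs are IUPAC patterns (e.g. `WGATAR` for GATA factors)
scanned on both strands with overlapping matches counted.  Significance
uses a matched null: per replicate, each peak is replaced by a uniformly
drawn same-chromosome region of identical width whose mean mappability and
GC lie within ±0.05 (tolerances doubled with a warning, at most 4 times,
if a peak is unmatchable), and the per-replicate motif-bearing proportion
is recomputed; the default is 10,000 replicates.  The empirical p-value
counts null proportions ≥ the observed one — with ≥ rather than the
strict > so that an absent motif yields p = 1 instead of a spurious 0.
Each peak's draws come from a stream seeded by (seed, chromosome, start,
width), making the p-value deterministic and invariant to peak order.
Null sampling is with replacement; a region may repeat within a replicate.

TSS aggregation profiles average strand-oriented bin windows (±2 kb
default) across genes and subtract the mean of the boundary bins (two per
end by default; four available via the `normalization` parameter — both
conventions appear in the source material, so neither is guessed as the
intent).

## Synthetic data

The generator emulates: random base composition; duplicated blocks copied
with per-base substitution rate 1 − identity (segmental-duplication-like
when ≥ 1 kb and ≥ 90% identity); point-source binding — each peak read's
fragment covers the peak summit, giving the canonical triangular coverage;
strand-symmetric single-end k-mer tags read off either fragment end; a
matched input sample with uniform fragment starts; and i.i.d. substitution
sequencing error (default 0 so that alignment ambiguity is exact by
construction).  The toy aligner is exhaustive over both strands and
therefore agrees with a position-by-position scan by definition.

It does not emulate: PCR duplicates, non-uniform fragment-length
distributions, realistic base-call error profiles, chromatin accessibility
biases, or paired-end reads.  Passing tests therefore demonstrate the
correctness and the qualitative behaviour of the method (uni-read analyses
cannot see exact-duplication peaks; fractional allocation can), not
performance on real libraries.

The standard benchmark (`benchmark_dataset`) is one 220 kb chromosome with
an exact 20 kb duplication, 10 unique-region and 10 duplicated-region
peaks of 1.5% read share each (30% of reads in peaks), and ChIP/input
depths of 20,000 36-mers with L = 200 — sizes chosen so every pipeline
stage runs in seconds while peak bins comfortably clear the 30-count
filter at the standard FDR of 0.05.  The model-based caller's
parameter-recovery checks use a separate bin-level simulator
(`simulate_bin_counts`, 50,000 bins, mappability coefficient 3.0, 5%
bound) drawn from the mixture model itself.

## Numerical choices and degenerate inputs

* Weight serialization at 6 decimals; conservation rechecked at 1e-5 after
  parsing, at 1e-9 internally.
* Pseudo-read ties at exactly 0.5/0.5 resolve to the smallest
  (chromosome, start); a read never emits two pseudo-reads.
* Empty bin tables yield empty peak lists; unknown chromosomes in window
  queries warn and return 0; zero uni-reads make the rescued percentage
  NaN, not an error.
* Rounding "to the nearest integer" is half-away-from-zero.
* The NB-mixture EM declares convergence when mean absolute responsibility
  change < 1e-4, capped at 50 iterations with a warning flag on the fit.

## Known limitations

* The allocation is the heuristic iterated-rescue scheme, not a full
  generative likelihood; quality scores and mismatch counts do not enter
  the weights.
* The mixture caller is a single-dataset simplification of the published
  estimator (no per-chromosome fits, fixed shift, moment-based dispersion).
* Occurrence counting keeps the whole k-mer dictionary in memory —
  appropriate for the megabase scale this package targets, not for
  gigabase genomes.
* Paired-end data and overlapping/sliding bins are out of scope.
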