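# multichip

Multi-mapping read allocation and peak calling for ChIP-seq in repetitive
genomes.

## The problem

Standard ChIP-seq pipelines keep only uniquely mapping tags (*uni-reads*).
Segmental duplications — repeats of ≥ 1 kb with ≥ 90% identity — produce
tags that align to several genomic locations (*multi-reads*) and are thrown
away, so binding sites inside duplicated sequence are systematically
invisible no matter how deep the sequencing.  `multichip` recovers those
sites by allocating each multi-read fractionally across its candidate
alignments and carrying the fractional counts through binning, peak
calling, and the downstream analyses needed to tell real duplicated-region
peaks from allocation artifacts.

## The method

**Allocation.** Every read keeps all alignments with at most 2 mismatches
(reads with ≥ 100 alignments are dropped).  Strand is ignored and each
alignment is identified by its leftmost coordinate *p*.  Starting from
uniform fractions 1/k, the weight of candidate *p_i* is updated
synchronously for a fixed number of iterations (default 200):

    f(p_i)  ∝  N(p_i, w),      N(p, w) = Σ counts over [p − w, p + w]

where the counts are the previous iteration's complete fractional count
field (uni-reads contribute weight 1 throughout) and *w* is a window
half-width (default 100 bp, constrained by 2w ≤ fragment length).  An
iterated "rescue": candidates near uniquely mapping mass capture their
read's weight geometrically.  The count field lives in a Fenwick-tree index
over the positions where at least one alignment starts (O(log n) updates
and window sums); a mathematically identical vectorized engine is the
default at desk scale.

**Mappability and binning.**  Per-position mappability is 1/n(x) for a
k-mer occurring n(x) < 100 times over both strands (Def 2; Def 1 is the
uniqueness indicator), extended over all fragment starts covering a
position, and averaged per bin together with GC content.  Reads are
extended strand-aware to the fragment length L (default 200 bp) and each
alignment adds its weight to every bin (default 200 bp) its fragment
overlaps; fractional totals are rounded to integers.

**Peak calling.**  Either (a) the conditional binomial test — under no
binding, ChIP count X given total X+Y is Binomial(X+Y, p0) with p0
estimated from bins with total count ≤ 1 — with Benjamini–Hochberg FDR, or
(b) a two-component mixture: a negative-binomial background regression on
mappability, a piecewise-linear GC spline, and log(1+input), plus a
shifted two-NB signal component, fit by EM, with direct posterior-based
FDR.  Bound bins below 30 ChIP tags are dropped; contiguous bound bins
merge into peaks.

**Downstream.**  UR/MR peak-set comparison (< 20-read support defines
"only" peaks); a multi-read similarity score s(i,j) = Σ_shared
(1 − |w_ri − w_rj|) with Type-I/II/III classification of MR-only peaks;
nested-subsample saturation curves; promoter/genic/duplication location
categories; consensus-motif counting with a width/mappability/GC-matched
null; and TSS aggregation profiles.  A pseudo-read exporter emits each
multi-read once at its maximum-weight location (weight ≥ 0.5) for
uni-read-only tools.

## Worked example

Everything is testable without downloads: the `simulate` module builds
genomes with planted duplications and binding sites.  The standard
benchmark is a 220 kb chromosome with an exact 20 kb duplication, 10 peaks
in unique sequence and 10 inside the duplicated block:

```python
import multichip as mc

bench = mc.benchmark_dataset(seed=11)
weights = mc.allocate_multireads(bench.chip_sets)
print(mc.allocation_summary(weights))
# n_uni          14462.000000
# n_multi         5538.000000
# pct_rescued       38.293459

mapp, gc = mc.covariate_bins(bench.genome, bench.read_length)
ur_peaks, ur_bins, *_ = mc.run_peak_calling(
    bench.chip_sets, bench.input_sets, bench.chrom_lengths, mapp, gc,
    mode="UR", method="cb")
mr_peaks, mr_bins, chip_w, _ = mc.run_peak_calling(
    bench.chip_sets, bench.input_sets, bench.chrom_lengths, mapp, gc,
    mode="MR", method="cb")
print(len(ur_peaks), len(mr_peaks))   # 10 30

comp = mc.compare_peak_sets(ur_peaks, mr_peaks, ur_bins, mr_bins)
print(len(comp.common_mr), len(comp.mr_only))   # 10 20

profiles = mc.peak_read_profiles(mr_peaks, chip_w)
ids = [f"{p.chrom}:{p.start}-{p.end}" for p in comp.mr_only]
cls = mc.classify_mr_only(ids, profiles)
print(cls.counts().to_dict())   # {'Type-I': 20}
```

Reading the numbers: 5,538 of 20,000 ChIP reads are multi-reads (a 38%
gain in depth over the 14,462 uni-reads).  The uni-read analysis finds only
the 10 unique-region peaks; the multi-read analysis finds all 20 planted
peaks plus the 10 mirror images inside the duplication's second copy.  All
20 MR-only peaks classify as Type-I — each shares essentially all of its
multi-reads, at symmetric 0.5/0.5 weights, with its mirror across the exact
duplication, which is precisely the duplication-artifact signature the
classification is built to flag.

A `multichip` CLI wraps the same pipeline (`multichip allocate`, `bins`,
`callpeaks`, `compare`, `classify`, `saturate`, `annotate`, `motif-null`,
`tss-profile`, `pseudo-reads`, `simulate`, `mappability`); every subcommand
is a thin layer over the functions above.

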