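"""Synthetic genomes, ChIP-seq reads, and a toy exhaustive multi-mapper.

The generator builds small genomes containing duplicated blocks (exact or
90-99% identical, i.e. segmental-duplication-like), plants point-source
binding peaks — some inside duplications — and sequences strand-aware
fragments of length L as k-mer single-end tags, together with a matched
input sample whose fragments start uniformly over the genome.  Every other
module of the package is testable against the returned ground truth without
any external download.

Fragments covering a peak are drawn so that the fragment always spans the
peak summit (start uniform in [summit-L+1, summit]), which yields the usual
triangular coverage profile around a point binding site.  Sequencing error
is i.i.d. substitution at a configurable rate, default 0, so that alignment
ambiguity in fixtures is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import CandidateAlignment, Interval, IntervalSet, ParseSummary, ReadAlignmentSet

__all__ = [
    "Duplication",
    "SyntheticGenomeSpec",
    "PlantedPeak",
    "SyntheticTruth",
    "simulate_genome",
    "simulate_chipseq",
    "exact_multimap",
    "simulate_bin_counts",
    "benchmark_dataset",
    "BenchmarkData",
]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Duplication:
    """Copy genome[chrom][start:end] to target_start with the given identity."""

    chrom: str
    start: int
    end: int
    target_chrom: str
    target_start: int
    identity: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.identity <= 1.0):
            raise ValueError("identity must be in (0, 1]")
        if self.end <= self.start:
            raise ValueError("empty duplication block")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_segdup(self) -> bool:
        # segmental duplications: >= 1 kb blocks with >= 90% identity
        return self.length >= 1000 and self.identity >= 0.9


@dataclass
class SyntheticGenomeSpec:
    chrom_lengths: dict[str, int]
    duplications: list[Duplication] = field(default_factory=list)
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0


def simulate_genome(spec: SyntheticGenomeSpec) -> tuple[dict[str, str], IntervalSet]:
    """Generate a random genome and copy in the requested duplication blocks.

    Returns the genome and an IntervalSet covering both the source and the
    target of every duplication (label "segdup" for blocks meeting the
    segmental-duplication definition, "dup" otherwise).  Target placements
    that overlap one another or a source block raise.
    """
    rng = np.random.default_rng(spec.seed)
    genome = {
        chrom: "".join(rng.choice(_BASES, size=n, p=spec.base_probs))
        for chrom, n in spec.chrom_lengths.items()
    }
    taken: list[Interval] = []
    for dup in spec.duplications:
        if dup.end > spec.chrom_lengths[dup.chrom]:
            raise ValueError(f"duplication source outside genome: {dup}")
        if dup.target_start + dup.length > spec.chrom_lengths[dup.target_chrom]:
            raise ValueError(f"duplication target outside genome: {dup}")
        tgt = Interval(dup.target_chrom, dup.target_start, dup.target_start + dup.length)
        src = Interval(dup.chrom, dup.start, dup.end)
        for prev in taken:
            if tgt.overlaps(prev):
                raise ValueError(f"overlapping duplication placement: {dup}")
        taken.extend([tgt, src])
        block = list(genome[dup.chrom][dup.start : dup.end])
        if dup.identity < 1.0:
            sub = rng.random(dup.length) < (1.0 - dup.identity)
            for i in np.flatnonzero(sub):
                block[i] = rng.choice([b for b in "ACGT" if b != block[i]])
        seq = genome[dup.target_chrom]
        genome[dup.target_chrom] = (
            seq[: dup.target_start] + "".join(block) + seq[dup.target_start + dup.length :]
        )
    blocks = IntervalSet(
        [
            iv
            for dup in spec.duplications
            for iv in (
                Interval(dup.chrom, dup.start, dup.end, "segdup" if dup.is_segdup else "dup"),
                Interval(
                    dup.target_chrom,
                    dup.target_start,
                    dup.target_start + dup.length,
                    "segdup" if dup.is_segdup else "dup",
                ),
            )
        ]
    )
    return genome, blocks


@dataclass(frozen=True)
class PlantedPeak:
    """A planted binding site; ``weight`` is its expected share of all reads."""

    chrom: str
    start: int
    end: int
    weight: float

    @property
    def summit(self) -> int:
        return (self.start + self.end) // 2

    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, "peak")


@dataclass
class SyntheticTruth:
    peaks: list[PlantedPeak]
    origins: list[tuple[str, int, str]]  # (chrom, leftmost read coordinate, strand)
    fragment_starts: list[tuple[str, int]]
    background_weight: float
    fragment_length: int
    read_length: int


def _draw_reads(
    genome: dict[str, str],
    peaks: Sequence[PlantedPeak],
    depth: int,
    read_length: int,
    fragment_length: int,
    error_rate: float,
    rng: np.random.Generator,
    prefix: str,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    k, L = read_length, fragment_length
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    bg_weight = 1.0 - sum(p.weight for p in peaks)
    if bg_weight < 0:
        raise ValueError("peak weights sum to more than 1")
    for p in peaks:
        if p.chrom not in genome or p.end > len(genome[p.chrom]) or p.start < 0:
            raise ValueError(f"planted peak outside genome: {p}")

    probs = np.array([p.weight for p in peaks] + [bg_weight])
    counts = rng.multinomial(depth, probs / probs.sum())
    reads: list[tuple[str, str]] = []
    origins: list[tuple[str, int, str]] = []
    frag_starts: list[tuple[str, int]] = []
    ridx = 0
    for src, n in enumerate(counts):
        for _ in range(n):
            if src < len(peaks):
                p = peaks[src]
                lo = max(0, p.summit - L + 1)
                hi = min(len(genome[p.chrom]) - L, p.summit)
                fs = int(rng.integers(lo, hi + 1))
                chrom = p.chrom
            else:
                ci = rng.choice(len(chroms), p=(lengths - L) / (lengths - L).sum())
                chrom = chroms[ci]
                fs = int(rng.integers(0, len(genome[chrom]) - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                seq = genome[chrom][fs : fs + k]
                origin = fs
            else:
                seq = revcomp(genome[chrom][fs + L - k : fs + L])
                origin = fs + L - k
            if error_rate > 0:
                err = rng.random(k) < error_rate
                if err.any():
                    s = list(seq)
                    for i in np.flatnonzero(err):
                        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
                    seq = "".join(s)
            reads.append((f"{prefix}{ridx}", seq))
            origins.append((chrom, origin, strand))
            frag_starts.append((chrom, fs))
            ridx += 1
    truth = SyntheticTruth(
        peaks=list(peaks),
        origins=origins,
        fragment_starts=frag_starts,
        background_weight=bg_weight,
        fragment_length=L,
        read_length=k,
    )
    return reads, truth


def simulate_chipseq(
    genome: dict[str, str],
    peaks: Sequence[PlantedPeak],
    depth: int,
    read_length: int = 36,
    fragment_length: int = 200,
    error_rate: float = 0.0,
    input_depth: int | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], SyntheticTruth]:
    """Simulate a ChIP sample plus a matched input (uniform-origin) sample.

    Returns (chip_reads, input_reads, truth); each read list holds
    (read_id, sequence) pairs and has exactly the requested depth.
    """
    if fragment_length < read_length:
        raise ValueError("fragment_length must be >= read_length")
    rng = np.random.default_rng(seed)
    chip, truth = _draw_reads(
        genome, peaks, depth, read_length, fragment_length, error_rate, rng, "chip_"
    )
    inp, _ = _draw_reads(
        genome, [], input_depth if input_depth is not None else depth,
        read_length, fragment_length, error_rate, rng, "input_",
    )
    return chip, inp, truth


def _kmer_positions(genome: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((chrom, i))
    return index


def _hamming_hits(seq: str, genome: dict[str, str], max_mm: int) -> list[tuple[str, int, int]]:
    k = len(seq)
    q = np.frombuffer(seq.encode(), dtype=np.uint8)
    hits = []
    for chrom, ref in genome.items():
        g = np.frombuffer(ref.encode(), dtype=np.uint8)
        n = len(g) - k + 1
        if n <= 0:
            continue
        mm = np.zeros(n, dtype=np.int32)
        for j in range(k):
            mm += g[j : j + n] != q[j]
        for pos in np.flatnonzero(mm <= max_mm):
            hits.append((chrom, int(pos), int(mm[pos])))
    return hits


def exact_multimap(
    reads: Sequence[tuple[str, str]],
    genome: dict[str, str],
    max_mismatches: int = 0,
    max_hits: int = 100,
) -> tuple[list[ReadAlignmentSet], ParseSummary]:
    """Report every alignment of each read on both strands, up to max_mismatches.

    A stand-in aligner for fixtures: exhaustive, hence guaranteed to agree
    with a position-by-position scan.  Reads with ``max_hits`` or more
    alignments are dropped and counted; unalignable reads are simply absent.
    """
    summary = ParseSummary()
    sets: list[ReadAlignmentSet] = []
    kmer_index = _kmer_positions(genome, len(reads[0][1])) if reads and max_mismatches == 0 else None
    for read_id, seq in reads:
        k = len(seq)
        alns: list[CandidateAlignment] = []
        if max_mismatches == 0 and kmer_index is not None:
            for chrom, pos in kmer_index.get(seq, []):
                alns.append(CandidateAlignment(read_id, chrom, pos, k, "+", 0))
            for chrom, pos in kmer_index.get(revcomp(seq), []):
                alns.append(CandidateAlignment(read_id, chrom, pos, k, "-", 0))
        else:
            for chrom, pos, mm in _hamming_hits(seq, genome, max_mismatches):
                alns.append(CandidateAlignment(read_id, chrom, pos, k, "+", mm))
            for chrom, pos, mm in _hamming_hits(revcomp(seq), genome, max_mismatches):
                alns.append(CandidateAlignment(read_id, chrom, pos, k, "-", mm))
        if not alns:
            continue
        alns.sort(key=lambda a: (a.reference, a.start, a.strand))
        summary.n_records += len(alns)
        if len(alns) >= max_hits:
            summary.n_dropped_max_hits += 1
            continue
        sets.append(ReadAlignmentSet(read_id=read_id, alignments=tuple(alns)))
        summary.n_reads_kept += 1
        if len(alns) == 1:
            summary.n_uni += 1
        else:
            summary.n_multi += 1
    return sets, summary


def simulate_bin_counts(
    n_bins: int = 50_000,
    mappability_coef: float = 3.0,
    intercept: float = 0.5,
    gc_coefs: tuple[float, float, float] = (1.0, -1.5, -1.0),
    input_coef: float = 0.6,
    dispersion: float = 0.2,
    bound_fraction: float = 0.05,
    signal_means: tuple[float, float] = (40.0, 150.0),
    signal_mix: float = 0.6,
    signal_size: float = 4.0,
    shift: int = 3,
    seed: int = 0,
):
    """Simulate a bin table from the two-component background/signal model.

    Background ChIP counts follow a negative binomial whose log mean is
    linear in mappability, a piecewise-linear GC spline (knots at the GC
    first and third quartiles), and log(1 + input); bound bins add a
    shift plus a two-component NB signal.  Returns (bins DataFrame,
    bound indicator array); used for parameter-recovery and FDR checks of
    the model-based caller.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    mapp = rng.uniform(0.0, 1.0, n_bins)
    gc = np.clip(rng.beta(6, 8, n_bins), 0.01, 0.99)
    q1, q3 = np.quantile(gc, [0.25, 0.75])
    inp = rng.poisson(8.0, n_bins)
    eta = (
        intercept
        + mappability_coef * mapp
        + gc_coefs[0] * gc
        + gc_coefs[1] * np.maximum(gc - q1, 0.0)
        + gc_coefs[2] * np.maximum(gc - q3, 0.0)
        + input_coef * np.log1p(inp)
    )
    mu = np.exp(eta)
    size = 1.0 / dispersion
    bg = rng.negative_binomial(size, size / (size + mu))
    bound = rng.random(n_bins) < bound_fraction
    comp = rng.random(n_bins) < signal_mix
    smean = np.where(comp, signal_means[0], signal_means[1])
    signal = shift + rng.negative_binomial(
        signal_size, signal_size / (signal_size + smean)
    )
    chip = np.where(bound, bg + signal, bg)
    bins = pd.DataFrame(
        {
            "chrom": "sim",
            "start": np.arange(n_bins) * 200,
            "chip_fractional": chip.astype(float),
            "chip_count": chip.astype(int),
            "input_count": inp.astype(int),
            "mappability": mapp,
            "gc": gc,
        }
    )
    return bins, bound


@dataclass
class BenchmarkData:
    """The standard desk-scale benchmark: genome + duplication + planted peaks."""

    genome: dict[str, str]
    dup_blocks: IntervalSet
    unique_peaks: list[PlantedPeak]
    dup_peaks: list[PlantedPeak]       # planted inside the duplication source copy
    chip_sets: list[ReadAlignmentSet]
    input_sets: list[ReadAlignmentSet]
    chip_summary: ParseSummary
    input_summary: ParseSummary
    truth: SyntheticTruth
    read_length: int
    fragment_length: int

    @property
    def peaks(self) -> list[PlantedPeak]:
        return self.unique_peaks + self.dup_peaks

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def benchmark_dataset(
    seed: int = 11,
    chrom_length: int = 220_000,
    dup_source: tuple[int, int] = (150_000, 170_000),
    dup_target: int = 190_000,
    n_unique_peaks: int = 10,
    n_dup_peaks: int = 10,
    depth: int = 20_000,
    input_depth: int = 20_000,
    read_length: int = 36,
    fragment_length: int = 200,
    peak_weight: float = 0.015,
) -> BenchmarkData:
    """Build the standard 220 kb single-chromosome benchmark.

    One 20 kb exact duplication; 10 peaks in unique sequence and 10 inside
    the duplication's source copy; ChIP and input depths of 20,000 36-mers
    each with fragment length 200 and 30% of ChIP reads in peaks.  All reads
    are aligned exhaustively with zero mismatches, so reads from the
    duplicated block map to exactly two locations.
    """
    rng = np.random.default_rng(seed)
    spec = SyntheticGenomeSpec(
        chrom_lengths={"chr1": chrom_length},
        duplications=[
            Duplication("chr1", dup_source[0], dup_source[1], "chr1", dup_target, 1.0)
        ],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    genome, blocks = simulate_genome(spec)

    # peak placement: unique-region peaks spread with >= 2 kb spacing,
    # duplicated-region peaks in the interior of the source copy
    uniq_pos = np.linspace(5_000, 140_000, n_unique_peaks).astype(int)
    uniq_pos = uniq_pos + rng.integers(-500, 500, n_unique_peaks)
    dup_lo, dup_hi = dup_source[0] + 1_000, dup_source[1] - 1_000
    dup_pos = np.linspace(dup_lo, dup_hi, n_dup_peaks).astype(int)
    dup_pos = dup_pos + rng.integers(-300, 300, n_dup_peaks)
    unique_peaks = [
        PlantedPeak("chr1", int(p) - 100, int(p) + 100, peak_weight) for p in uniq_pos
    ]
    dup_peaks = [
        PlantedPeak("chr1", int(p) - 100, int(p) + 100, peak_weight) for p in dup_pos
    ]
    chip_reads, input_reads, truth = simulate_chipseq(
        genome,
        unique_peaks + dup_peaks,
        depth=depth,
        read_length=read_length,
        fragment_length=fragment_length,
        input_depth=input_depth,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    chip_sets, chip_summary = exact_multimap(chip_reads, genome)
    input_sets, input_summary = exact_multimap(input_reads, genome)
    return BenchmarkData(
        genome=genome,
        dup_blocks=blocks,
        unique_peaks=unique_peaks,
        dup_peaks=dup_peaks,
        chip_sets=chip_sets,
        input_sets=input_sets,
        chip_summary=chip_summary,
        input_summary=input_summary,
        truth=truth,
        read_length=read_length,
        fragment_length=fragment_length,
    )
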