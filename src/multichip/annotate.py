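"""Peak annotation, consensus-motif counting, matched-null enrichment, and
TSS aggregation profiles.

Peaks are assigned to exactly one of six location categories with the
precedence PromDup > Prom > GenicDup > Genic > Dup > None:

* Prom  — overlapping a promoter window (+/- ``promoter_halfwidth`` of a
  TSS; the halfwidth is a configurable choice, default 2 kb);
* Genic — overlapping a gene's extended genic window, 10 kb upstream of the
  TSS to 1 kb downstream of the TES (strand-oriented);
* the ...Dup variants apply when either the matched gene or the peak itself
  overlaps a segmental duplication;
* Dup   — in a segmental duplication but neither promoter nor genic;
* None  — nothing above.

Motif enrichment is assessed against a matched null: for each peak, a
random same-chromosome region of identical width whose mean mappability and
GC content are within a tolerance of the peak's is drawn; the proportion of
regions containing the consensus is recomputed per replicate, and the
empirical p-value is the fraction of replicates strictly exceeding the
observed proportion.
"""

from __future__ import annotations

import re
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Interval, IntervalSet
from .peaks import Peak
from .simulate import revcomp

__all__ = [
    "GenomeAnnotation",
    "NullSamplingParams",
    "AggregateProfile",
    "annotate_peaks",
    "count_consensus",
    "matched_null_test",
    "tss_profile",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def iupac_regex(pattern: str) -> str:
    try:
        return "".join(_IUPAC[c] for c in pattern.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in pattern") from exc


@dataclass
class GenomeAnnotation:
    """Gene records plus segmental duplications and window parameters.

    ``genes`` must have columns chrom, tss, tes, strand, gene_id; TSS/TES
    are genomic coordinates of the transcription start/end (for minus-strand
    genes the TSS is the larger coordinate).
    """

    genes: pd.DataFrame
    segdups: IntervalSet = field(default_factory=IntervalSet)
    promoter_halfwidth: int = 2000
    genic_upstream: int = 10_000
    genic_downstream: int = 1000

    def promoter_window(self, row) -> tuple[int, int]:
        return max(0, row.tss - self.promoter_halfwidth), row.tss + self.promoter_halfwidth

    def genic_window(self, row) -> tuple[int, int]:
        if row.strand == "+":
            lo = row.tss - self.genic_upstream
            hi = row.tes + self.genic_downstream
        else:
            lo = row.tes - self.genic_downstream
            hi = row.tss + self.genic_upstream
        return max(0, lo), hi

    def gene_body(self, row) -> tuple[int, int]:
        return min(row.tss, row.tes), max(row.tss, row.tes) + 1


def _overlaps(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> bool:
    return a_lo < b_hi and b_lo < a_hi


def annotate_peaks(
    peaks: Sequence[Peak], annotation: GenomeAnnotation
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign each peak one location category; returns (table, percentages)."""
    categories = []
    for p in peaks:
        in_dup = bool(annotation.segdups.overlapping(p.chrom, p.start, p.end))
        prom = prom_dup = genic = genic_dup = False
        for row in annotation.genes.itertuples():
            if row.chrom != p.chrom:
                continue
            g_lo, g_hi = annotation.gene_body(row)
            gene_dup = bool(annotation.segdups.overlapping(row.chrom, g_lo, g_hi))
            dup_qualifier = gene_dup or in_dup
            lo, hi = annotation.promoter_window(row)
            if _overlaps(p.start, p.end, lo, hi):
                prom = True
                prom_dup = prom_dup or dup_qualifier
            lo, hi = annotation.genic_window(row)
            if _overlaps(p.start, p.end, lo, hi):
                genic = True
                genic_dup = genic_dup or dup_qualifier
        if prom and prom_dup:
            cat = "PromDup"
        elif prom:
            cat = "Prom"
        elif genic and genic_dup:
            cat = "GenicDup"
        elif genic:
            cat = "Genic"
        elif in_dup:
            cat = "Dup"
        else:
            cat = "None"
        categories.append(cat)
    table = pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "category": categories,
        }
    )
    order = ["PromDup", "Prom", "GenicDup", "Genic", "Dup", "None"]
    pct = (
        table["category"].value_counts().reindex(order, fill_value=0) / max(len(peaks), 1) * 100.0
    )
    return table, pct


def count_consensus(
    peaks: Sequence[Peak], genome: dict[str, str], pattern: str
) -> tuple[np.ndarray, float]:
    """Count consensus occurrences per peak on both strands (overlaps counted).

    Returns the per-peak counts and the proportion of peaks containing at
    least one occurrence.
    """
    fwd = re.compile(f"(?=({iupac_regex(pattern)}))")
    rev = re.compile(f"(?=({iupac_regex(revcomp_pattern(pattern))}))")
    counts = np.zeros(len(peaks), dtype=int)
    for i, p in enumerate(peaks):
        seq = genome[p.chrom][p.start : p.end]
        counts[i] = len(fwd.findall(seq)) + len(rev.findall(seq))
    prop = float(np.mean(counts > 0)) if len(peaks) else 0.0
    return counts, prop


_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_pattern(pattern: str) -> str:
    return pattern.upper().translate(_IUPAC_COMP)[::-1]


@dataclass
class NullSamplingParams:
    n_sets: int = 10_000
    mappability_tol: float = 0.05
    gc_tol: float = 0.05
    same_chromosome: bool = True
    max_tolerance_widenings: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mappability_tol <= 0 or self.gc_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class MatchedNullResult:
    p_value: float
    observed_proportion: float
    null_proportions: np.ndarray
    n_sets: int


def _per_position(bins: pd.DataFrame, column: str, chrom: str, length: int, bin_size: int) -> np.ndarray:
    """Expand a bin-level column into a per-position array (NaN where absent)."""
    arr = np.full(length, np.nan)
    sub = bins[bins["chrom"] == chrom]
    for start, value in zip(sub["start"], sub[column]):
        arr[start : start + bin_size] = value
    return arr


def matched_null_test(
    peaks: Sequence[Peak],
    genome: dict[str, str],
    mappability_bins: pd.DataFrame,
    gc_bins: pd.DataFrame,
    pattern: str,
    params: NullSamplingParams | None = None,
    bin_size: int = 200,
) -> MatchedNullResult:
    """Empirical motif-enrichment p-value against width/mappability/GC-matched
    random regions.

    Deterministic under ``params.seed`` and invariant to peak ordering: each
    peak's null regions are drawn from a stream seeded by (seed, chromosome,
    start, width).  If no candidate matches a peak at the stated tolerances,
    they are doubled (with a warning) up to ``max_tolerance_widenings``
    times before erroring.
    """
    params = params or NullSamplingParams()
    if not peaks:
        raise ValueError("no peaks supplied")
    pat_len = len(pattern)
    # per-chromosome prefix structures
    motif_prefix: dict[str, np.ndarray] = {}
    mapp_prefix: dict[str, np.ndarray] = {}
    gc_prefix: dict[str, np.ndarray] = {}
    fwd = re.compile(f"(?=({iupac_regex(pattern)}))")
    rev = re.compile(f"(?=({iupac_regex(revcomp_pattern(pattern))}))")
    for chrom in {p.chrom for p in peaks}:
        seq = genome[chrom]
        hit = np.zeros(len(seq) + 1)
        for m in fwd.finditer(seq):
            hit[m.start()] = 1
        for m in rev.finditer(seq):
            hit[m.start()] = 1
        motif_prefix[chrom] = np.concatenate(([0.0], np.cumsum(hit[:-1])))
        mp = _per_position(mappability_bins, "mappability", chrom, len(seq), bin_size)
        gp = _per_position(gc_bins, "gc", chrom, len(seq), bin_size)
        mapp_prefix[chrom] = np.concatenate(([0.0], np.cumsum(np.nan_to_num(mp))))
        gc_prefix[chrom] = np.concatenate(([0.0], np.cumsum(np.nan_to_num(gp))))

    def region_mean(prefix: np.ndarray, s: np.ndarray, width: int) -> np.ndarray:
        return (prefix[s + width] - prefix[s]) / width

    def region_has_motif(chrom: str, s: np.ndarray, width: int) -> np.ndarray:
        hi = np.minimum(s + width - pat_len + 1, len(motif_prefix[chrom]) - 1)
        hi = np.maximum(hi, s)
        return (motif_prefix[chrom][hi] - motif_prefix[chrom][s]) > 0

    obs_hits = []
    null_matrix = np.zeros((params.n_sets, len(peaks)), dtype=bool)
    for j, p in enumerate(peaks):
        chrom = p.chrom
        width = p.end - p.start
        seqlen = len(genome[chrom])
        starts = np.arange(0, seqlen - width + 1)
        target_m = region_mean(mapp_prefix[chrom], np.array([p.start]), width)[0]
        target_g = region_mean(gc_prefix[chrom], np.array([p.start]), width)[0]
        obs_hits.append(bool(region_has_motif(chrom, np.array([p.start]), width)[0]))
        m_tol, g_tol = params.mappability_tol, params.gc_tol
        cand = np.array([], dtype=int)
        for attempt in range(params.max_tolerance_widenings + 1):
            mm = region_mean(mapp_prefix[chrom], starts, width)
            gg = region_mean(gc_prefix[chrom], starts, width)
            ok = (np.abs(mm - target_m) <= m_tol) & (np.abs(gg - target_g) <= g_tol)
            cand = starts[ok]
            if len(cand):
                break
            warnings.warn(
                f"no matched null region for peak {chrom}:{p.start}-{p.end}; "
                f"doubling tolerances", stacklevel=2,
            )
            m_tol, g_tol = 2 * m_tol, 2 * g_tol
        if not len(cand):
            raise ValueError(f"unmatchable peak {chrom}:{p.start}-{p.end}")
        peak_seed = zlib.crc32(f"{chrom}:{p.start}:{width}".encode()) & 0x7FFFFFFF
        rng = np.random.default_rng([params.seed, peak_seed])
        draws = cand[rng.integers(0, len(cand), size=params.n_sets)]
        null_matrix[:, j] = region_has_motif(chrom, draws, width)

    observed = float(np.mean(obs_hits))
    null_props = null_matrix.mean(axis=1)
    # null sets matching the observed proportion count against enrichment, so
    # a motif absent from the genome yields p = 1, not spurious significance
    p_value = float(np.mean(null_props >= observed))
    return MatchedNullResult(
        p_value=p_value,
        observed_proportion=observed,
        null_proportions=null_props,
        n_sets=params.n_sets,
    )


@dataclass
class AggregateProfile:
    offsets: np.ndarray  # bp relative to TSS, strand-oriented bin starts
    values: np.ndarray
    n_genes: int
    n_skipped: int
    normalization: int


def tss_profile(
    bins: pd.DataFrame,
    column: str,
    genes: pd.DataFrame,
    flank: int = 2000,
    bin_size: int = 200,
    normalization: int = 2,
) -> AggregateProfile:
    """Strand-oriented mean signal around TSSs, boundary-normalized.

    Each gene contributes the ``2*flank/bin_size`` bins around its TSS
    (reversed for minus-strand genes); the cross-gene mean is normalized by
    subtracting the average of ``normalization`` bins at each end of the
    profile.  Genes whose window leaves the covered bin range are skipped
    and counted.
    """
    nb = flank // bin_size
    tracks: dict[str, np.ndarray] = {}
    for chrom, sub in bins.groupby("chrom"):
        n = int(sub["start"].max()) // bin_size + 1
        arr = np.full(n, np.nan)
        arr[(sub["start"] // bin_size).to_numpy()] = sub[column].to_numpy()
        tracks[chrom] = arr
    rows = []
    skipped = 0
    for row in genes.itertuples():
        track = tracks.get(row.chrom)
        if track is None:
            skipped += 1
            continue
        tb = row.tss // bin_size
        lo, hi = tb - nb, tb + nb
        if lo < 0 or hi > len(track):
            skipped += 1
            continue
        window = track[lo:hi]
        if np.isnan(window).any():
            skipped += 1
            continue
        if row.strand == "-":
            window = window[::-1]
        rows.append(window)
    if not rows:
        values = np.zeros(2 * nb)
    else:
        mean = np.mean(rows, axis=0)
        boundary = np.concatenate([mean[:normalization], mean[-normalization:]]).mean()
        values = mean - boundary
    offsets = (np.arange(-nb, nb)) * bin_size
    return AggregateProfile(
        offsets=offsets,
        values=values,
        n_genes=len(rows),
        n_skipped=skipped,
        normalization=normalization,
    )
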