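"""Genome mappability and GC-content tracks.

Two per-nucleotide definitions are supported, both driven by the number of
times n(x) the k-mer starting at x occurs in the genome over both strands:

* ``def1`` (uni-read mappability): 1 if n(x) == 1, else 0 — a position can
  contribute uniquely mapping tags or not;
* ``def2`` (multi-read-aware): 1/n(x) if 1 <= n(x) < 100, else 0 — k-mers
  mapping to fewer than 100 locations can still generate non-zero fractional
  counts once multi-reads are allocated, with mass diluted by 1/n.

Because fragment extension lets counts at x arise from forward-strand tags
starting in the L positions up to and including x, and from reverse-strand
tags whose 5' ends sit in the L positions from x rightwards, the extended
score at x averages the relevant per-start scores, with denominators
truncated to the starts actually inside the chromosome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import revcomp

__all__ = [
    "MappabilityTrack",
    "kmer_occurrences",
    "nucleotide_mappability",
    "fragment_extend_mappability",
    "bin_scores",
    "gc_bins",
]


@dataclass
class MappabilityTrack:
    scores: dict[str, np.ndarray]  # per-position, length == chromosome length
    definition: str
    k: int
    extended: bool = False
    fragment_length: int | None = None


def kmer_occurrences(genome: dict[str, str], k: int) -> dict[str, np.ndarray]:
    """Count, for every position x, occurrences of its k-mer over both strands.

    Positions whose k-mer contains N (or that are within k-1 of the 3' end
    and so start no full k-mer) get the sentinel 0.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    for chrom, seq in genome.items():
        if k > len(seq):
            raise ValueError(f"k={k} exceeds length of {chrom}")
    counts: Counter[str] = Counter()
    for seq in genome.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    occ: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        n = np.zeros(len(seq), dtype=np.int64)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            n[i] = counts[kmer] + counts[revcomp(kmer)]
        occ[chrom] = n
    return occ


def nucleotide_mappability(
    occurrences: dict[str, np.ndarray],
    definition: str = "def2",
    k: int | None = None,
    max_locations: int = 100,
) -> MappabilityTrack:
    """Per-position mappability from occurrence counts.

    def1: indicator of unique k-mers.  def2: 1/n for n below
    ``max_locations`` (the multi-read retention cap), else 0.
    """
    scores: dict[str, np.ndarray] = {}
    for chrom, n in occurrences.items():
        if definition == "def1":
            s = (n == 1).astype(float)
        elif definition == "def2":
            with np.errstate(divide="ignore"):
                s = np.where((n >= 1) & (n < max_locations), 1.0 / np.maximum(n, 1), 0.0)
        else:
            raise ValueError(f"unknown mappability definition {definition!r}")
        scores[chrom] = s
    return MappabilityTrack(scores=scores, definition=definition, k=k or 0)


def fragment_extend_mappability(track: MappabilityTrack, L: int) -> MappabilityTrack:
    """Average per-start scores over all fragment starts covering each position.

    Forward-strand tags starting in [x-L+1, x] and reverse-strand tags with
    5' ends in [x, x+L-1] both deposit extended-fragment counts on x.  The
    reverse-strand score of a 5' end y equals the forward score of the
    k-mer's leftmost coordinate y-k+1 (both-strand occurrence counting makes
    the two identical), so the reverse contribution at x is the forward
    score summed over starts [x-k+1, x+L-k].  Denominators count only
    in-chromosome contributing starts, which truncates cleanly at the ends.
    """
    if track.extended:
        raise ValueError("track is already fragment-extended")
    k = track.k
    if k <= 0:
        raise ValueError("track must carry its k-mer length")
    if L < k:
        raise ValueError("fragment length must be >= tag length")
    out: dict[str, np.ndarray] = {}
    for chrom, s in track.scores.items():
        n = len(s)
        last = n - k  # last valid forward start
        valid = np.zeros(n)
        valid[: last + 1] = 1.0
        sv = s * valid
        cs = np.concatenate(([0.0], np.cumsum(sv)))
        cv = np.concatenate(([0.0], np.cumsum(valid)))

        def rngsum(arr, lo, hi):
            # inclusive [lo, hi] clipped to [0, n-1]
            lo = np.clip(lo, 0, n)
            hi = np.clip(hi + 1, 0, n)
            return arr[hi] - arr[lo]

        x = np.arange(n)
        num = rngsum(cs, x - L + 1, x) + rngsum(cs, x - k + 1, x + L - k)
        den = rngsum(cv, x - L + 1, x) + rngsum(cv, x - k + 1, x + L - k)
        with np.errstate(invalid="ignore", divide="ignore"):
            ext = np.where(den > 0, num / den, 0.0)
        out[chrom] = ext
    return MappabilityTrack(
        scores=out, definition=track.definition, k=k, extended=True, fragment_length=L
    )


def _tile(n: int, bin_size: int) -> np.ndarray:
    return np.arange(0, n, bin_size)


def bin_scores(
    track: MappabilityTrack, bin_size: int, genome: dict[str, str] | None = None
) -> pd.DataFrame:
    """Average a per-position track into non-overlapping tiling bins.

    If the genome is supplied, bins consisting solely of the ambiguous base
    N are excluded, matching the bin-table convention used downstream.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    rows = []
    for chrom, s in track.scores.items():
        starts = _tile(len(s), bin_size)
        for b in starts:
            seg = s[b : b + bin_size]
            if genome is not None:
                bases = genome[chrom][b : b + bin_size]
                if set(bases) == {"N"}:
                    continue
            rows.append((chrom, int(b), float(seg.mean())))
    return pd.DataFrame(rows, columns=["chrom", "start", "mappability"])


def gc_bins(genome: dict[str, str], bin_size: int) -> pd.DataFrame:
    """Per-bin GC fraction among non-N bases; all-N bins are excluded."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    rows = []
    for chrom, seq in genome.items():
        for b in _tile(len(seq), bin_size):
            window = seq[b : b + bin_size]
            acgt = sum(1 for c in window if c != "N")
            if acgt == 0:
                continue
            gc = sum(1 for c in window if c in "GC") / acgt
            rows.append((chrom, int(b), gc))
    return pd.DataFrame(rows, columns=["chrom", "start", "gc"])
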