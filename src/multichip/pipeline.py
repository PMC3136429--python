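"""End-to-end wiring: alignment sets -> allocation -> bins -> peaks.

Convenience layer used by the CLI, the saturation analysis, and the
benchmark scripts; every step is the corresponding module's public API.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .allocate import AllocationParams, allocate_multireads
from .binning import BinningParams, assemble_bintable, extend_and_bin
from .io import ReadAlignmentSet, WeightedAlignment
from .mappability import (
    bin_scores,
    fragment_extend_mappability,
    gc_bins,
    kmer_occurrences,
    nucleotide_mappability,
)
from .peaks import Peak, PeakCallParams, call_peaks, cb_test, fit_nb_mixture

__all__ = ["covariate_bins", "build_bin_table", "run_peak_calling"]


def covariate_bins(
    genome: dict[str, str],
    k: int,
    bin_size: int = 200,
    fragment_length: int = 200,
    definition: str = "def2",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bin-level (mappability, gc) covariates for a genome and tag length."""
    occ = kmer_occurrences(genome, k)
    track = nucleotide_mappability(occ, definition=definition, k=k)
    track = fragment_extend_mappability(track, fragment_length)
    return bin_scores(track, bin_size, genome=genome), gc_bins(genome, bin_size)


def build_bin_table(
    chip_weights: Sequence[WeightedAlignment],
    input_weights: Sequence[WeightedAlignment],
    chrom_lengths: dict[str, int],
    mappability: pd.DataFrame,
    gc: pd.DataFrame,
    mode: str = "MR",
    binning: BinningParams | None = None,
) -> pd.DataFrame:
    binning = binning or BinningParams()
    chip = extend_and_bin(chip_weights, chrom_lengths, binning, mode=mode)
    inp = extend_and_bin(input_weights, chrom_lengths, binning, mode=mode)
    return assemble_bintable(chip, inp, mappability, gc)


def run_peak_calling(
    chip_sets: Sequence[ReadAlignmentSet],
    input_sets: Sequence[ReadAlignmentSet],
    chrom_lengths: dict[str, int],
    mappability: pd.DataFrame,
    gc: pd.DataFrame,
    mode: str = "MR",
    method: str = "cb",
    fdr: float = 0.05,
    min_chip_count: int = 30,
    allocation: AllocationParams | None = None,
    binning: BinningParams | None = None,
) -> tuple[list[Peak], pd.DataFrame, list[WeightedAlignment], list[WeightedAlignment]]:
    """Full pipeline; returns (peaks, bin table, chip weights, input weights).

    In UR mode allocation is skipped (uni-reads only, weight 1); in MR mode
    multi-reads are allocated first and contribute fractional counts.
    """
    allocation = allocation or AllocationParams()
    binning = binning or BinningParams()
    if mode == "UR":
        chip_w = [
            _uni_weight(s) for s in chip_sets if s.is_uni
        ]
        input_w = [_uni_weight(s) for s in input_sets if s.is_uni]
    else:
        chip_w = allocate_multireads(chip_sets, allocation)
        input_w = allocate_multireads(input_sets, allocation)
    bins = build_bin_table(
        chip_w, input_w, chrom_lengths, mappability, gc, mode=mode, binning=binning
    )
    params = PeakCallParams(fdr=fdr, min_chip_count=min_chip_count, method=method)
    if method == "cb":
        scores = cb_test(bins)
    else:
        scores = fit_nb_mixture(bins)
    peaks = call_peaks(scores, bins, params, bin_size=binning.bin_size)
    return peaks, bins, chip_w, input_w


def _uni_weight(s: ReadAlignmentSet) -> WeightedAlignment:
    a = s.alignments[0]
    return WeightedAlignment(
        read_id=a.read_id,
        reference=a.reference,
        start=a.start,
        length=a.length,
        strand=a.strand,
        weight=1.0,
        mismatches=a.mismatches,
        n_candidates=1,
    )
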