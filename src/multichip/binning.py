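"""Fragment extension and bin-level count tables.

Weighted alignments are extended strand-aware to the expected fragment
length L (forward: [start, start+L); reverse: [end-L, end), clipped at
chromosome boundaries) and each alignment's weight is added to every bin its
fragment overlaps.  Fractional totals are then converted to integer counts
by rounding to the nearest integer (half away from zero) by default, with
ceiling and floor available as the upper/lower-bound alternatives.

The assembled bin table (ChIP fractional + integer counts, input counts,
mean mappability, GC fraction per bin) is the common input of both peak
callers.  A UR table uses uni-reads only; an MR table uses uni-reads plus
allocated multi-reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import WeightedAlignment

__all__ = ["BinningParams", "extend_and_bin", "assemble_bintable", "BIN_COLUMNS"]

BIN_COLUMNS = [
    "chrom",
    "start",
    "chip_fractional",
    "chip_count",
    "input_count",
    "mappability",
    "gc",
]


@dataclass
class BinningParams:
    bin_size: int = 200  # matched to the expected fragment length
    fragment_length: int = 200
    rounding: str = "round"

    def __post_init__(self) -> None:
        if self.rounding not in ("round", "ceiling", "floor"):
            raise ValueError(f"unknown rounding {self.rounding!r}")
        if not 50 <= self.bin_size <= 250:
            warnings.warn(
                f"bin_size {self.bin_size} outside the usual 50-250 bp working range",
                stacklevel=2,
            )


def apply_rounding(fractional: np.ndarray, rounding: str) -> np.ndarray:
    # fractional sums are rounded at 9 decimals first so that accumulation
    # noise (e.g. 0.6 + 0.4 -> 1.0000000000000002) cannot leak into ceil/floor
    x = np.round(fractional, 9)
    if rounding == "round":
        return np.floor(x + 0.5).astype(int)  # half away from zero (counts >= 0)
    if rounding == "ceiling":
        return np.ceil(x).astype(int)
    if rounding == "floor":
        return np.floor(x).astype(int)
    raise ValueError(f"unknown rounding {rounding!r}")


def extend_and_bin(
    weights: Sequence[WeightedAlignment],
    chrom_lengths: dict[str, int],
    params: BinningParams | None = None,
    mode: str = "MR",
) -> pd.DataFrame:
    """Accumulate fragment-extended weights into tiling bins.

    In UR mode only uni-reads (single candidate alignment, weight 1) are
    used; in MR mode every weighted alignment contributes its weight to all
    bins overlapped by its extended fragment.  Returns a table with one row
    per bin (all bins of the tiling, zero rows included) and columns
    chrom, start, fractional, count.
    """
    params = params or BinningParams()
    if mode not in ("UR", "MR"):
        raise ValueError(f"unknown mode {mode!r}")
    b = params.bin_size
    L = params.fragment_length
    acc = {
        chrom: np.zeros((n + b - 1) // b) for chrom, n in chrom_lengths.items()
    }
    for w in weights:
        if mode == "UR" and w.n_candidates != 1:
            continue
        n = chrom_lengths[w.reference]
        if w.strand == "+":
            s, e = w.start, w.start + L
        else:
            s, e = w.end - L, w.end
        s, e = max(0, s), min(n, e)  # clip at chromosome boundaries
        if e <= s:
            continue
        acc[w.reference][s // b : (e - 1) // b + 1] += w.weight
    rows = []
    for chrom in sorted(chrom_lengths):
        starts = np.arange(len(acc[chrom])) * b
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "fractional": acc[chrom]}
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out["count"] = apply_rounding(out["fractional"].to_numpy(), params.rounding)
    return out


def assemble_bintable(
    chip_bins: pd.DataFrame,
    input_bins: pd.DataFrame,
    mappability_bins: pd.DataFrame,
    gc_bins: pd.DataFrame,
) -> pd.DataFrame:
    """Join ChIP, input, mappability, and GC tracks on bin coordinates.

    ChIP and input must share an identical tiling; the mappability/GC tables
    may lack all-N bins, which are then absent from the result, but any
    coordinate in them that is not part of the ChIP tiling (a shifted
    tiling) is an error.
    """
    key = ["chrom", "start"]
    chip_keys = set(map(tuple, chip_bins[key].itertuples(index=False)))
    input_keys = set(map(tuple, input_bins[key].itertuples(index=False)))
    if chip_keys != input_keys:
        raise ValueError("ChIP and input bin tilings differ")
    for name, other in (("mappability", mappability_bins), ("gc", gc_bins)):
        extra = set(map(tuple, other[key].itertuples(index=False))) - chip_keys
        if extra:
            raise ValueError(f"{name} bins not aligned with count tiling (e.g. {sorted(extra)[0]})")
    out = chip_bins.rename(
        columns={"fractional": "chip_fractional", "count": "chip_count"}
    )[key + ["chip_fractional", "chip_count"]]
    out = out.merge(
        input_bins.rename(columns={"count": "input_count"})[key + ["input_count"]],
        on=key,
        how="inner",
    )
    out = out.merge(mappability_bins, on=key, how="inner")
    out = out.merge(gc_bins, on=key, how="inner")
    return out.sort_values(key).reset_index(drop=True)
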