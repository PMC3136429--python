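"""Alignment, interval, and sequence I/O.

Coordinates are 0-based half-open internally.  SAM is read and written
1-based per the standard (pysam handles the conversion); BED is 0-based.
Multi-alignments are accepted either as repeated SAM records per read or as
secondary-alignment-flagged records; both are grouped by read id in memory,
so input does not have to be sorted by read id.

Weighted alignments carry the allocation probability of each candidate
mapping.  Two on-disk dialects are supported:

* ``bed-weight-column`` -- tab text with columns
  ``chrom start end read_id mismatches strand weight n_candidates``
  (weight serialized at 6 decimals);
* ``tagged-sam`` -- SAM records with the weight in the ``XW`` float tag and
  the number of candidate alignments in the standard ``NH`` tag.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from pyfaidx import Fasta

__all__ = [
    "CandidateAlignment",
    "ReadAlignmentSet",
    "WeightedAlignment",
    "Interval",
    "IntervalSet",
    "ParseSummary",
    "parse_alignments",
    "write_weighted_alignments",
    "read_weighted_alignments",
    "pseudo_reads",
    "export_pseudo_reads",
    "read_intervals",
    "write_intervals",
    "read_genome",
    "write_genome",
    "write_reads_fasta",
]

#: per-read weight conservation tolerance applied after parsing
WEIGHT_TOL = 1e-5


@dataclass(frozen=True)
class CandidateAlignment:
    """One candidate mapping of a read.

    ``start`` is the 0-based leftmost genomic coordinate of the alignment;
    by convention the leftmost coordinate is the alignment's starting
    position regardless of strand.
    """

    read_id: str
    reference: str
    start: int
    length: int
    strand: str
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for read {self.read_id}")
        if self.length <= 0:
            raise ValueError(f"non-positive length for read {self.read_id}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class ReadAlignmentSet:
    """All retained candidate alignments of one read."""

    read_id: str
    alignments: tuple[CandidateAlignment, ...]

    def __post_init__(self) -> None:
        if not self.alignments:
            raise ValueError(f"read {self.read_id} has no alignments")
        for aln in self.alignments:
            if aln.read_id != self.read_id:
                raise ValueError("alignment read_id mismatch")
            if aln.length != self.alignments[0].length:
                raise ValueError("alignments of one read must share length")

    @property
    def is_uni(self) -> bool:
        return len(self.alignments) == 1

    def __len__(self) -> int:
        return len(self.alignments)


@dataclass(frozen=True)
class WeightedAlignment:
    """A candidate alignment together with its allocation probability."""

    read_id: str
    reference: str
    start: int
    length: int
    strand: str
    weight: float
    mismatches: int = 0
    n_candidates: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0 + 1e-9):
            raise ValueError(f"weight {self.weight} outside [0, 1]")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def is_uni(self) -> bool:
        return self.n_candidates == 1


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    label: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative interval start: {self}")
        if self.end <= self.start:
            raise ValueError(f"inverted/empty interval: {self}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class IntervalSet:
    """An ordered collection of labelled half-open genomic intervals."""

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        self.intervals: list[Interval] = list(intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def overlapping(self, chrom: str, start: int, end: int) -> list[Interval]:
        probe = Interval(chrom, start, end)
        return [iv for iv in self.intervals if iv.overlaps(probe)]

    def validate_against(self, chrom_lengths: dict[str, int]) -> None:
        for iv in self.intervals:
            if iv.chrom not in chrom_lengths or iv.end > chrom_lengths[iv.chrom]:
                raise ValueError(f"interval {iv} outside genome")


@dataclass
class ParseSummary:
    n_records: int = 0
    n_reads_kept: int = 0
    n_uni: int = 0
    n_multi: int = 0
    n_dropped_max_hits: int = 0
    n_dropped_mismatches: int = 0


def _group_records(records: Iterable[CandidateAlignment]) -> "OrderedDict[str, list[CandidateAlignment]]":
    groups: OrderedDict[str, list[CandidateAlignment]] = OrderedDict()
    for rec in records:
        groups.setdefault(rec.read_id, []).append(rec)
    return groups


def _iter_sam_records(path: str) -> Iterator[CandidateAlignment]:
    with pysam.AlignmentFile(path, check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped:
                continue
            length = rec.query_length or rec.infer_read_length()
            if not length:
                length = rec.reference_length or 0
            mism = rec.get_tag("NM") if rec.has_tag("NM") else 0
            yield CandidateAlignment(
                read_id=rec.query_name,
                reference=rec.reference_name,
                start=rec.reference_start,
                length=int(length),
                strand="-" if rec.is_reverse else "+",
                mismatches=int(mism),
            )


def _iter_bed_records(path: str) -> Iterator[CandidateAlignment]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 tab-separated fields")
            try:
                chrom, start, end, name, score, strand = parts[:6]
                start_i, end_i = int(start), int(end)
                yield CandidateAlignment(
                    read_id=name,
                    reference=chrom,
                    start=start_i,
                    length=end_i - start_i,
                    strand=strand,
                    mismatches=int(score),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record ({exc})") from exc


def parse_alignments(
    path: str,
    format: str = "sam",
    max_hits: int = 100,
    max_mismatches: int = 2,
) -> tuple[list[ReadAlignmentSet], ParseSummary]:
    """Parse a multi-alignment file into per-read alignment sets.

    Reads with ``max_hits`` or more alignments surviving the mismatch filter
    are dropped entirely, as are reads whose alignments all exceed
    ``max_mismatches``; both are tallied in the returned summary.
    """
    if format in ("sam", "bam"):
        records = _iter_sam_records(path)
    elif format == "bed-text":
        records = _iter_bed_records(path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")

    summary = ParseSummary()
    sets: list[ReadAlignmentSet] = []
    for read_id, alns in _group_records(records).items():
        summary.n_records += len(alns)
        kept = [a for a in alns if a.mismatches <= max_mismatches]
        if not kept:
            summary.n_dropped_mismatches += 1
            continue
        if len(kept) >= max_hits:
            summary.n_dropped_max_hits += 1
            continue
        sets.append(ReadAlignmentSet(read_id=read_id, alignments=tuple(kept)))
        summary.n_reads_kept += 1
        if len(kept) == 1:
            summary.n_uni += 1
        else:
            summary.n_multi += 1
    return sets, summary


def check_conservation(
    weights: Sequence[WeightedAlignment], tol: float = WEIGHT_TOL
) -> None:
    """Raise if any read's weights do not sum to 1 within ``tol``."""
    sums: dict[str, float] = {}
    for w in weights:
        sums[w.read_id] = sums.get(w.read_id, 0.0) + w.weight
    bad = {r: s for r, s in sums.items() if abs(s - 1.0) > tol}
    if bad:
        worst = max(bad.items(), key=lambda kv: abs(kv[1] - 1.0))
        raise ValueError(
            f"per-read weight conservation violated for {len(bad)} reads "
            f"(worst: {worst[0]} sums to {worst[1]:.8f})"
        )


def write_weighted_alignments(
    weights: Sequence[WeightedAlignment],
    path: str,
    dialect: str = "bed-weight-column",
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Persist weighted alignments; round-trips (reference, start, strand, weight)."""
    check_conservation(weights)
    if dialect == "bed-weight-column":
        with open(path, "w") as out:
            for w in weights:
                out.write(
                    f"{w.reference}\t{w.start}\t{w.end}\t{w.read_id}\t"
                    f"{w.mismatches}\t{w.strand}\t{w.weight:.6f}\t{w.n_candidates}\n"
                )
    elif dialect == "tagged-sam":
        if chrom_lengths is None:
            raise ValueError("tagged-sam output requires chrom_lengths for the header")
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
        }
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for w in weights:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = w.read_id
                rec.reference_name = w.reference
                rec.reference_start = w.start
                rec.cigarstring = f"{w.length}M"
                rec.flag = 16 if w.strand == "-" else 0
                rec.mapping_quality = 255
                rec.set_tags(
                    [("NM", w.mismatches, "i"), ("NH", w.n_candidates, "i"),
                     ("XW", round(w.weight, 6), "f")]
                )
                out.write(rec)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_weighted_alignments(
    path: str, dialect: str = "bed-weight-column"
) -> list[WeightedAlignment]:
    out: list[WeightedAlignment] = []
    if dialect == "bed-weight-column":
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 8:
                    raise ValueError(f"{path}:{lineno}: expected 8 fields")
                chrom, start, end, name, mism, strand, weight, ncand = parts
                out.append(
                    WeightedAlignment(
                        read_id=name,
                        reference=chrom,
                        start=int(start),
                        length=int(end) - int(start),
                        strand=strand,
                        weight=float(weight),
                        mismatches=int(mism),
                        n_candidates=int(ncand),
                    )
                )
    elif dialect == "tagged-sam":
        with pysam.AlignmentFile(path, check_sq=False) as handle:
            for rec in handle:
                out.append(
                    WeightedAlignment(
                        read_id=rec.query_name,
                        reference=rec.reference_name,
                        start=rec.reference_start,
                        length=rec.query_alignment_length or rec.infer_read_length(),
                        strand="-" if rec.is_reverse else "+",
                        weight=float(rec.get_tag("XW")),
                        mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                        n_candidates=int(rec.get_tag("NH")) if rec.has_tag("NH") else 1,
                    )
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    check_conservation(out)
    return out


def pseudo_reads(weights: Sequence[WeightedAlignment]) -> list[WeightedAlignment]:
    """Collapse each read to at most one unweighted pseudo-read.

    Uni-reads pass through unchanged.  A multi-read is emitted only at its
    maximum-weight location and only when that weight rounds up, i.e. is at
    least 0.5; an exact 0.5/0.5 tie is resolved to the smallest
    (chromosome, start) so a read is never counted twice.
    """
    by_read: OrderedDict[str, list[WeightedAlignment]] = OrderedDict()
    for w in weights:
        by_read.setdefault(w.read_id, []).append(w)
    out: list[WeightedAlignment] = []
    for read_id, alns in by_read.items():
        if len(alns) == 1 and alns[0].n_candidates == 1:
            out.append(alns[0])
            continue
        # deterministic argmax: max weight, ties by smallest (chrom, start)
        maxw = max(a.weight for a in alns)
        ties = [a for a in alns if a.weight == maxw]
        best = min(ties, key=lambda a: (a.reference, a.start))
        if maxw >= 0.5:
            out.append(
                WeightedAlignment(
                    read_id=read_id,
                    reference=best.reference,
                    start=best.start,
                    length=best.length,
                    strand=best.strand,
                    weight=1.0,
                    mismatches=best.mismatches,
                    n_candidates=best.n_candidates,
                )
            )
    return out


def export_pseudo_reads(weights: Sequence[WeightedAlignment], path: str) -> list[WeightedAlignment]:
    """Write pseudo-reads as unweighted BED6 records; returns the emitted list."""
    check_conservation(weights)
    selected = pseudo_reads(weights)
    with open(path, "w") as out:
        for w in selected:
            out.write(f"{w.reference}\t{w.start}\t{w.end}\t{w.read_id}\t{w.mismatches}\t{w.strand}\n")
    return selected


def read_intervals(path: str) -> IntervalSet:
    """Read a BED file (0-based half-open) into an IntervalSet."""
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 fields")
            try:
                iv = Interval(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    label=parts[3] if len(parts) > 3 else ".",
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return IntervalSet(intervals)


def write_intervals(intervals: IntervalSet, path: str) -> None:
    with open(path, "w") as out:
        for iv in intervals:
            out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_genome(path: str) -> dict[str, str]:
    """Load a FASTA genome into an in-memory dict of upper-case sequences."""
    fasta = Fasta(path, sequence_always_upper=True)
    return {name: str(fasta[name][:]) for name in fasta.keys()}


def write_genome(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_reads_fasta(reads: Sequence[tuple[str, str]], path: str) -> None:
    with open(path, "w") as out:
        for name, seq in reads:
            out.write(f">{name}\n{seq}\n")
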