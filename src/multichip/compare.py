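"""UR/MR peak-set comparison, multi-read similarity, and saturation.

An MR-only peak is an MR peak with no UR-peak overlap whose UR read support
is below a count threshold (default 20), making it essentially undetectable
from uni-reads; UR-only is symmetric.  MR-only peaks are then screened by
the structure of the multi-reads they share with other peaks:

* Type-III — shares no multi-reads with any other peak;
* Type-II  — shares multi-reads but is independently supported: (a) at
  least 20 units of fractional multi-read mass not shared with its
  maximum-similarity partner, or (b) at least 20 uni-reads, or (c) an
  unshared-to-shared fractional mass ratio of at least 2;
* Type-I   — everything else: peaks that mirror another peak's multi-reads
  with similar weights, the signature of a segmental-duplication artifact.

The similarity between two peaks sums, over shared reads, 1 - |w_i - w_j|,
where w is the read's combined weight inside each peak: identical halves
(0.5/0.5) contribute fully, strongly asymmetric allocations (0.9/0.1)
barely.  Self-similarity is then exactly the number of reads in the peak.
Normalization divides by the larger read count of the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ReadAlignmentSet, WeightedAlignment
from .peaks import Peak

__all__ = [
    "PeakSetComparison",
    "PeakReadProfile",
    "SimilarityRecord",
    "MROnlyClassification",
    "compare_peak_sets",
    "peak_read_profiles",
    "similarity",
    "classify_mr_only",
    "nested_subsamples",
    "saturation",
]


def _peak_read_count(peak: Peak, bins: pd.DataFrame, bin_size: int) -> int:
    sel = (
        (bins["chrom"] == peak.chrom)
        & (bins["start"] + bin_size > peak.start)
        & (bins["start"] < peak.end)
    )
    return int(bins.loc[sel, "chip_count"].sum())


@dataclass
class PeakSetComparison:
    common_ur: list[Peak]
    common_mr: list[Peak]
    mr_only: list[Peak]
    ur_only: list[Peak]
    ambiguous: list[Peak]
    threshold: int

    @property
    def common(self) -> list[Peak]:
        return self.common_ur + self.common_mr


def compare_peak_sets(
    ur_peaks: Sequence[Peak],
    mr_peaks: Sequence[Peak],
    ur_bins: pd.DataFrame,
    mr_bins: pd.DataFrame,
    threshold: int = 20,
    bin_size: int = 200,
) -> PeakSetComparison:
    """Partition the union of UR and MR peaks into common/only/ambiguous.

    Overlap (>= 1 bp) with the other list makes a peak common.  A
    non-overlapping MR peak is MR-only when the UR sample's read count over
    its span is below ``threshold``, otherwise ambiguous; symmetric for UR.
    """
    common_ur, common_mr, mr_only, ur_only, ambiguous = [], [], [], [], []
    for p in ur_peaks:
        if any(p.overlaps(q) for q in mr_peaks):
            common_ur.append(p)
        elif _peak_read_count(p, mr_bins, bin_size) < threshold:
            ur_only.append(p)
        else:
            ambiguous.append(p)
    for p in mr_peaks:
        if any(p.overlaps(q) for q in ur_peaks):
            common_mr.append(p)
        elif _peak_read_count(p, ur_bins, bin_size) < threshold:
            mr_only.append(p)
        else:
            ambiguous.append(p)
    return PeakSetComparison(
        common_ur=common_ur,
        common_mr=common_mr,
        mr_only=mr_only,
        ur_only=ur_only,
        ambiguous=ambiguous,
        threshold=threshold,
    )


@dataclass
class PeakReadProfile:
    """The collapsed read-weight set of one peak.

    A read belongs to the peak when any of its alignment intervals overlaps
    the peak region; multiple mappings of the same read inside the peak are
    collapsed with their weights summed.
    """

    peak_id: str
    weights: dict[str, float]
    uni_reads: set[str]
    multi_reads: set[str]

    @property
    def n_reads(self) -> int:
        return len(self.weights)

    @property
    def n_unireads(self) -> int:
        return len(self.uni_reads)

    @property
    def total_mass(self) -> float:
        return sum(self.weights.values())


def peak_read_profiles(
    peaks: Sequence[Peak], weights: Sequence[WeightedAlignment]
) -> dict[str, PeakReadProfile]:
    """Build one PeakReadProfile per peak (keyed "chrom:start-end")."""
    profiles: dict[str, PeakReadProfile] = {}
    for p in peaks:
        pid = f"{p.chrom}:{p.start}-{p.end}"
        profiles[pid] = PeakReadProfile(peak_id=pid, weights={}, uni_reads=set(), multi_reads=set())
    for w in weights:
        for p in peaks:
            if w.reference == p.chrom and w.start < p.end and p.start < w.end:
                pid = f"{p.chrom}:{p.start}-{p.end}"
                prof = profiles[pid]
                prof.weights[w.read_id] = prof.weights.get(w.read_id, 0.0) + w.weight
                (prof.uni_reads if w.n_candidates == 1 else prof.multi_reads).add(w.read_id)
    return profiles


@dataclass
class SimilarityRecord:
    peak_i: str
    peak_j: str
    n_shared: int
    unnormalized: float
    normalized: float
    t_pvalue: float  # NaN when fewer than 2 shared reads
    wilcoxon_pvalue: float


def similarity(profile_i: PeakReadProfile, profile_j: PeakReadProfile) -> SimilarityRecord:
    """Shared-read similarity plus paired tests on the shared weight pairs.

    The paired t-test and Wilcoxon signed-rank test ask whether shared
    multi-reads carry the same average weight in the two peaks; with fewer
    than two shared reads (or degenerate differences for Wilcoxon) the
    p-values are reported as NaN.
    """
    if profile_i.peak_id == profile_j.peak_id:
        shared = list(profile_i.weights)
    else:
        shared = [r for r in profile_i.weights if r in profile_j.weights]
    wi = np.array([profile_i.weights[r] for r in shared])
    wj = np.array([profile_j.weights[r] for r in shared])
    unnorm = float(np.sum(1.0 - np.abs(wi - wj)))
    denom = max(profile_i.n_reads, profile_j.n_reads)
    norm = unnorm / denom if denom else 0.0
    t_p = w_p = float("nan")
    if len(shared) >= 2 and profile_i.peak_id != profile_j.peak_id:
        if np.ptp(wi - wj) > 0 or np.any(wi != wj):
            t_p = float(stats.ttest_rel(wi, wj).pvalue)
            try:
                w_p = float(stats.wilcoxon(wi, wj, zero_method="zsplit").pvalue)
            except ValueError:
                w_p = float("nan")
        else:
            t_p = w_p = 1.0
    return SimilarityRecord(
        peak_i=profile_i.peak_id,
        peak_j=profile_j.peak_id,
        n_shared=len(shared),
        unnormalized=unnorm,
        normalized=norm,
        t_pvalue=t_p,
        wilcoxon_pvalue=w_p,
    )


@dataclass
class MROnlyClassification:
    types: dict[str, str]  # peak id -> Type-I / Type-II / Type-III
    criteria: dict[str, str]  # peak id -> a / b / c / none
    partners: dict[str, str | None]

    def counts(self) -> pd.Series:
        return pd.Series(self.types).value_counts()


def classify_mr_only(
    mr_only_ids: Sequence[str],
    profiles: dict[str, PeakReadProfile],
    mass_threshold: float = 20.0,
    uniread_threshold: int = 20,
    ratio_threshold: float = 2.0,
) -> MROnlyClassification:
    """Classify MR-only peaks by their shared multi-reads.

    For each MR-only peak the criteria are evaluated against its
    maximum-normalized-similarity partner among all profiled peaks sharing
    at least one multi-read with it.
    """
    types: dict[str, str] = {}
    criteria: dict[str, str] = {}
    partners: dict[str, str | None] = {}
    for pid in mr_only_ids:
        prof = profiles[pid]
        best: tuple[float, str] | None = None
        for other_id, other in profiles.items():
            if other_id == pid:
                continue
            if prof.multi_reads & other.multi_reads:
                rec = similarity(prof, other)
                if best is None or rec.normalized > best[0]:
                    best = (rec.normalized, other_id)
        if best is None:
            types[pid] = "Type-III"
            criteria[pid] = "none"
            partners[pid] = None
            continue
        partner = profiles[best[1]]
        partners[pid] = best[1]
        shared = prof.multi_reads & partner.multi_reads
        unshared = prof.multi_reads - shared
        unshared_mass = sum(prof.weights[r] for r in unshared)
        shared_mass = sum(prof.weights[r] for r in shared)
        if unshared_mass >= mass_threshold:
            types[pid], criteria[pid] = "Type-II", "a"
        elif prof.n_unireads >= uniread_threshold:
            types[pid], criteria[pid] = "Type-II", "b"
        elif shared_mass > 0 and unshared_mass / shared_mass >= ratio_threshold:
            types[pid], criteria[pid] = "Type-II", "c"
        else:
            types[pid], criteria[pid] = "Type-I", "none"
    return MROnlyClassification(types=types, criteria=criteria, partners=partners)


def nested_subsamples(
    sets: Sequence[ReadAlignmentSet],
    fractions: Sequence[float],
    rng: np.random.Generator,
) -> dict[float, list[ReadAlignmentSet]]:
    """Nested subsamples: each read gets one uniform draw, kept when u <= f."""
    u = rng.random(len(sets))
    out: dict[float, list[ReadAlignmentSet]] = {}
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction {f} outside (0, 1]")
        out[f] = [s for s, ui in zip(sets, u) if ui <= f]
    return out


def saturation(
    uni_sets: Sequence[ReadAlignmentSet],
    multi_sets: Sequence[ReadAlignmentSet],
    fractions: Sequence[float],
    gold_peaks: Sequence[Peak],
    pipeline: Callable[[Sequence[ReadAlignmentSet], str], Sequence[Peak]],
    seed: int = 0,
    modes: Sequence[str] = ("UR", "MR"),
) -> pd.DataFrame:
    """Gold-peak recovery as a function of nested subsampled depth.

    Uni- and multi-reads are subsampled separately (nested across
    fractions); the UR sample at a fraction is the sampled uni-reads, the
    MR sample adds the sampled multi-reads.  ``pipeline(sets, mode)`` must
    re-run the full analysis and return peaks; recovery is the percentage
    of gold peaks overlapped (>= 1 bp) by the returned peaks.
    """
    rng = np.random.default_rng(seed)
    uni_sub = nested_subsamples(uni_sets, fractions, rng)
    multi_sub = nested_subsamples(multi_sets, fractions, rng)
    rows = []
    for f in fractions:
        for mode in modes:
            subset = list(uni_sub[f])
            if mode == "MR":
                subset += multi_sub[f]
            called = pipeline(subset, mode)
            if gold_peaks:
                hit = sum(1 for g in gold_peaks if any(g.overlaps(p) for p in called))
                recovery = 100.0 * hit / len(gold_peaks)
            else:
                recovery = float("nan")
            rows.append(
                {"mode": mode, "fraction": f, "recovery_pct": recovery, "n_peaks": len(called)}
            )
    return pd.DataFrame(rows)
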