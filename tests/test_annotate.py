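"""Location categories, consensus counting, matched-null motif test, TSS profiles."""

import numpy as np
import pandas as pd
import pytest

import multichip as mc
from multichip.annotate import revcomp_pattern
from multichip.io import Interval, IntervalSet
from multichip.peaks import Peak


def _peak(start, end, chrom="c"):
    return Peak(chrom, start, end, 1e-6, start, 100, 10, 2.0, 1.0, 0.5, 1)


def _genes(rows):
    return pd.DataFrame(rows, columns=["chrom", "tss", "tes", "strand", "gene_id"])


class TestAnnotatePeaks:
    def _annotation(self, segdups=()):
        genes = _genes(
            [
                ("c", 50_000, 60_000, "+", "gA"),  # inside the segdup below
                ("c", 200_000, 210_000, "+", "gB"),  # far from any segdup
            ]
        )
        return mc.GenomeAnnotation(
            genes=genes,
            segdups=IntervalSet([Interval("c", s, e, "segdup") for s, e in segdups]),
        )

    def test_promoter_of_duplicated_gene(self):
        ann = self._annotation(segdups=[(45_000, 70_000)])
        table, pct = mc.annotate_peaks([_peak(49_000, 49_400)], ann)
        assert table["category"].tolist() == ["PromDup"]

    def test_plain_promoter(self):
        ann = self._annotation()
        table, _ = mc.annotate_peaks([_peak(199_000, 199_400)], ann)
        assert table["category"].tolist() == ["Prom"]

    def test_genic_peak_inside_unrelated_segdup(self):
        # peak in gB's genic window while overlapping a segdup unrelated to gB
        ann = self._annotation(segdups=[(205_000, 207_000)])
        table, _ = mc.annotate_peaks([_peak(205_500, 205_900)], ann)
        assert table["category"].tolist() == ["GenicDup"]

    def test_bare_duplication_and_none(self):
        ann = self._annotation(segdups=[(400_000, 402_000)])
        table, _ = mc.annotate_peaks([_peak(400_100, 400_500), _peak(500_000, 500_200)], ann)
        assert table["category"].tolist() == ["Dup", "None"]

    def test_empty_segdups_collapse_categories_exactly(self):
        peaks = [
            _peak(49_000, 49_400),    # PromDup -> Prom
            _peak(205_500, 205_900),  # GenicDup -> Genic
            _peak(400_100, 400_500),  # Dup -> None
        ]
        with_dups = self._annotation(
            segdups=[(45_000, 70_000), (205_000, 207_000), (400_000, 402_000)]
        )
        without = self._annotation()
        got_with, _ = mc.annotate_peaks(peaks, with_dups)
        got_without, _ = mc.annotate_peaks(peaks, without)
        assert got_with["category"].tolist() == ["PromDup", "GenicDup", "Dup"]
        assert got_without["category"].tolist() == ["Prom", "Genic", "None"]

    def test_percentages_sum_to_100(self):
        ann = self._annotation(segdups=[(45_000, 70_000)])
        peaks = [_peak(49_000, 49_400), _peak(500_000, 500_200)]
        _, pct = mc.annotate_peaks(peaks, ann)
        assert pct.sum() == pytest.approx(100.0)


class TestCountConsensus:
    GATA = "WGATAR"  # [A/T]GATA[A/G]

    def _genome(self, seq):
        return {"c": seq}

    def test_forward_match(self):
        counts, prop = mc.count_consensus([_peak(0, 6)], self._genome("TGATAA"), self.GATA)
        assert counts.tolist() == [1] and prop == 1.0

    def test_no_match(self):
        counts, _ = mc.count_consensus([_peak(0, 6)], self._genome("GGATAA"), self.GATA)
        assert counts.tolist() == [0]

    def test_reverse_complement_match(self):
        counts, _ = mc.count_consensus([_peak(0, 6)], self._genome("TTATCA"), self.GATA)
        assert counts.tolist() == [1]

    def test_overlapping_matches_counted(self):
        # AGATAGATAA: AGATAG at 0 (WGATAR) and GATAGA? no; but ensure lookahead
        counts, _ = mc.count_consensus(
            [_peak(0, 12)], self._genome("TGATAATGATAA"), self.GATA
        )
        assert counts.tolist() == [2]

    def test_invalid_symbol_errors(self):
        with pytest.raises(ValueError, match="IUPAC"):
            mc.count_consensus([_peak(0, 6)], self._genome("ACGTAC"), "WGAT?R")

    def test_revcomp_pattern(self):
        assert revcomp_pattern("WGATAR") == "YTATCW"


@pytest.fixture(scope="module")
def motif_fixture():
    """Random genome with the GATA consensus planted at 20 peak centers."""
    rng = np.random.default_rng(41)
    spec = mc.SyntheticGenomeSpec(chrom_lengths={"m": 60_000}, seed=43)
    genome, _ = mc.simulate_genome(spec)
    seq = list(genome["m"])
    centers = np.linspace(2_000, 58_000, 20).astype(int)
    for c in centers:
        seq[c : c + 6] = "TGATAA"
    genome = {"m": "".join(seq)}
    peaks = [_peak(int(c) - 100, int(c) + 100, chrom="m") for c in centers]
    mapp = pd.DataFrame(
        {"chrom": "m", "start": np.arange(0, 60_000, 200), "mappability": 1.0}
    )
    gc = mc.gc_bins(genome, 200)
    return genome, peaks, mapp, gc


class TestMatchedNull:
    def test_planted_motifs_are_enriched(self, motif_fixture):
        genome, peaks, mapp, gc = motif_fixture
        params = mc.NullSamplingParams(n_sets=1000, seed=5)
        res = mc.matched_null_test(peaks, genome, mapp, gc, "WGATAR", params)
        assert res.observed_proportion == 1.0
        assert res.p_value <= 0.01

    def test_absent_pattern_gives_p_one(self, motif_fixture):
        genome, peaks, mapp, gc = motif_fixture
        # a 12-mer consensus essentially absent from a random 60 kb genome
        pattern = "ACGTACGTACGT"
        counts, prop = mc.count_consensus(peaks, genome, pattern)
        assert prop == 0.0
        params = mc.NullSamplingParams(n_sets=200, seed=5)
        res = mc.matched_null_test(peaks, genome, mapp, gc, pattern, params)
        assert res.p_value == 1.0

    def test_deterministic_and_order_invariant(self, motif_fixture):
        genome, peaks, mapp, gc = motif_fixture
        params = mc.NullSamplingParams(n_sets=300, seed=9)
        r1 = mc.matched_null_test(peaks, genome, mapp, gc, "WGATAR", params)
        r2 = mc.matched_null_test(peaks[::-1], genome, mapp, gc, "WGATAR", params)
        assert r1.p_value == r2.p_value
        assert np.allclose(np.sort(r1.null_proportions), np.sort(r2.null_proportions))


class TestTSSProfile:
    def _bins(self, values):
        return pd.DataFrame(
            {"chrom": "c", "start": np.arange(len(values)) * 200, "chip_count": values}
        )

    def test_constant_track_normalizes_to_zero(self):
        bins = self._bins(np.full(100, 7.0))
        genes = _genes([("c", 10_000, 12_000, "+", "g1")])
        prof = mc.tss_profile(bins, "chip_count", genes, flank=2000)
        assert np.allclose(prof.values, 0.0)

    def test_single_gene_equals_own_window(self):
        rng = np.random.default_rng(3)
        values = rng.random(100)
        bins = self._bins(values)
        genes = _genes([("c", 10_000, 12_000, "+", "g1")])
        prof = mc.tss_profile(bins, "chip_count", genes, flank=2000, normalization=2)
        window = values[40:60]
        expect = window - np.concatenate([window[:2], window[-2:]]).mean()
        assert np.allclose(prof.values, expect)

    def test_minus_strand_window_reversed(self):
        rng = np.random.default_rng(4)
        values = rng.random(100)
        bins = self._bins(values)
        plus = mc.tss_profile(bins, "chip_count",
                              _genes([("c", 10_000, 12_000, "+", "g")]), flank=2000)
        minus = mc.tss_profile(bins, "chip_count",
                               _genes([("c", 10_000, 8_000, "-", "g")]), flank=2000)
        assert np.allclose(minus.values, plus.values[::-1])

    def test_matches_loop_and_average_oracle(self):
        rng = np.random.default_rng(8)
        values = rng.random(500)
        bins = self._bins(values)
        tss = rng.integers(5_000, 95_000, 50)
        strands = rng.choice(["+", "-"], 50)
        genes = _genes([("c", int(t), int(t) + 1000, s, f"g{i}")
                        for i, (t, s) in enumerate(zip(tss, strands))])
        prof = mc.tss_profile(bins, "chip_count", genes, flank=2000, normalization=2)
        windows = []
        for t, s in zip(tss, strands):
            tb = t // 200
            win = values[tb - 10 : tb + 10]
            windows.append(win[::-1] if s == "-" else win)
        mean = np.mean(windows, axis=0)
        expect = mean - np.concatenate([mean[:2], mean[-2:]]).mean()
        assert np.allclose(prof.values, expect)
        assert prof.n_genes == 50

    def test_out_of_range_gene_skipped(self):
        bins = self._bins(np.ones(20))
        genes = _genes([("c", 100, 500, "+", "g1"), ("c", 2_000, 2_400, "+", "g2")])
        prof = mc.tss_profile(bins, "chip_count", genes, flank=2000)
        assert prof.n_genes == 1 and prof.n_skipped == 1
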