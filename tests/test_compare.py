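"""Peak-set comparison, multi-read similarity, Type classification, saturation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import multichip as mc
from multichip.compare import PeakReadProfile, nested_subsamples
from multichip.io import WeightedAlignment as WA
from multichip.peaks import Peak


def _peak(start, end, chrom="c"):
    return Peak(chrom, start, end, 1e-6, start, 100, 10, 2.0, 1.0, 0.5, (end - start) // 200)


def _bins(counts, start0=0):
    n = len(counts)
    return pd.DataFrame(
        {
            "chrom": "c",
            "start": start0 + np.arange(n) * 200,
            "chip_fractional": np.asarray(counts, float),
            "chip_count": counts,
            "input_count": 0,
            "mappability": 1.0,
            "gc": 0.5,
        }
    )


class TestComparePeakSets:
    def test_identical_lists_all_common(self):
        peaks = [_peak(0, 400), _peak(1000, 1200)]
        comp = mc.compare_peak_sets(peaks, peaks, _bins([0] * 10), _bins([0] * 10))
        assert len(comp.common) == 4 and not comp.mr_only and not comp.ur_only

    def test_mr_only_requires_low_ur_support(self):
        mr = [_peak(1000, 1200)]
        ur_bins = _bins([0, 0, 0, 0, 0, 19, 0, 0, 0, 0])  # 19 UR reads under the peak
        comp = mc.compare_peak_sets([], mr, ur_bins, _bins([0] * 10))
        assert comp.mr_only == mr and not comp.ambiguous

    def test_threshold_boundary_is_ambiguous(self):
        mr = [_peak(1000, 1200)]
        ur_bins = _bins([0, 0, 0, 0, 0, 20, 0, 0, 0, 0])
        comp = mc.compare_peak_sets([], mr, ur_bins, _bins([0] * 10))
        assert comp.ambiguous == mr and not comp.mr_only

    def test_partition_is_exhaustive(self):
        ur = [_peak(0, 200), _peak(5000, 5200)]
        mr = [_peak(100, 400), _peak(8000, 8200)]
        bins = _bins([0] * 50)
        comp = mc.compare_peak_sets(ur, mr, bins, bins)
        counted = (
            len(comp.common) + len(comp.mr_only) + len(comp.ur_only) + len(comp.ambiguous)
        )
        assert counted == len(ur) + len(mr)


class TestPeakReadProfiles:
    def test_within_peak_mappings_collapse(self):
        peak = _peak(0, 1000)
        ws = [
            WA("m1", "c", 100, 36, "+", 0.3, n_candidates=3),
            WA("m1", "c", 500, 36, "-", 0.2, n_candidates=3),
            WA("m1", "c", 90_000, 36, "+", 0.5, n_candidates=3),
            WA("u1", "c", 200, 36, "+", 1.0),
        ]
        prof = mc.peak_read_profiles([peak], ws)["c:0-1000"]
        assert prof.weights["m1"] == pytest.approx(0.5)
        assert prof.weights["u1"] == 1.0
        assert prof.n_reads == 2 and prof.n_unireads == 1

    def test_empty_profile(self):
        prof = mc.peak_read_profiles([_peak(0, 200)], [])["c:0-200"]
        assert prof.n_reads == 0 and prof.total_mass == 0.0


def _profile(pid, weights, uni=(), multi=None):
    multi = set(weights) - set(uni) if multi is None else set(multi)
    return PeakReadProfile(pid, dict(weights), set(uni), multi)


class TestSimilarity:
    def test_all_half_weights_give_overlap_count(self):
        a = _profile("a", {f"r{i}": 0.5 for i in range(7)})
        b = _profile("b", {f"r{i}": 0.5 for i in range(7)})
        rec = mc.similarity(a, b)
        assert rec.unnormalized == pytest.approx(7.0)
        assert rec.normalized == pytest.approx(1.0)

    def test_self_similarity_is_read_count(self):
        a = _profile("a", {"r1": 0.9, "r2": 0.4, "r3": 1.0}, uni={"r3"})
        rec = mc.similarity(a, a)
        assert rec.unnormalized == pytest.approx(3.0)

    def test_asymmetric_weights_reduce_similarity(self):
        a1 = _profile("a", {"r": 0.9})
        b1 = _profile("b", {"r": 0.1})
        a2 = _profile("a", {"r": 0.6})
        b2 = _profile("b", {"r": 0.4})
        assert mc.similarity(a1, b1).unnormalized == pytest.approx(0.2)
        assert mc.similarity(a2, b2).unnormalized == pytest.approx(0.8)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(1, 12))
            shared = {f"s{i}": rng.random() for i in range(n)}
            a = _profile("a", {**shared, "xa": rng.random()})
            b = _profile("b", {**{k: rng.random() for k in shared}, "xb": rng.random()})
            rab, rba = mc.similarity(a, b), mc.similarity(b, a)
            assert rab.unnormalized == pytest.approx(rba.unnormalized)
            assert rab.normalized == pytest.approx(rba.normalized)
            assert 0.0 <= rab.normalized <= 1.0

    def test_paired_tests_match_reference(self):
        rng = np.random.default_rng(29)
        for _ in range(100):
            n = int(rng.integers(3, 20))
            wi, wj = rng.random(n), rng.random(n)
            a = _profile("a", dict(zip([f"r{i}" for i in range(n)], wi)))
            b = _profile("b", dict(zip([f"r{i}" for i in range(n)], wj)))
            rec = mc.similarity(a, b)
            d = wi - wj
            t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p_ref = 2 * stats.t.sf(abs(t), n - 1)
            assert rec.t_pvalue == pytest.approx(p_ref, abs=1e-8)

    def test_too_few_shared_reads_gives_nan(self):
        a = _profile("a", {"r": 0.5})
        b = _profile("b", {"r": 0.5})
        rec = mc.similarity(a, b)
        assert np.isnan(rec.t_pvalue) and np.isnan(rec.wilcoxon_pvalue)


class TestClassifyMROnly:
    def test_hand_worked_outcomes(self):
        """Five constructed profiles exercising every class and criterion."""
        profiles = {
            # shares nothing with anyone -> Type-III
            "iso": _profile("iso", {"a1": 0.5, "a2": 0.5}),
            # 25 units of unshared multi-read mass -> Type-II via (a)
            "massive": _profile(
                "massive",
                {**{f"m{i}": 1.0 for i in range(25)}, "sh1": 0.5},
            ),
            # 20 uni-reads -> Type-II via (b)
            "unirich": _profile(
                "unirich",
                {**{f"u{i}": 1.0 for i in range(20)}, "sh2": 0.5},
                uni={f"u{i}" for i in range(20)},
            ),
            # unshared/shared multi mass ratio 3 >= 2 -> Type-II via (c)
            "ratio": _profile("ratio", {"x1": 0.9, "x2": 0.6, "sh3": 0.5}),
            # high similarity, no independent support -> Type-I
            "mirror": _profile("mirror", {"sh4": 0.5, "sh5": 0.5}),
            # partner peak sharing the sh* reads
            "partner": _profile(
                "partner", {"sh1": 0.5, "sh2": 0.5, "sh3": 0.5, "sh4": 0.5, "sh5": 0.5}
            ),
        }
        ids = ["iso", "massive", "unirich", "ratio", "mirror"]
        result = mc.classify_mr_only(ids, profiles)
        assert result.types == {
            "iso": "Type-III",
            "massive": "Type-II",
            "unirich": "Type-II",
            "ratio": "Type-II",
            "mirror": "Type-I",
        }
        assert result.criteria["massive"] == "a"
        assert result.criteria["unirich"] == "b"
        assert result.criteria["ratio"] == "c"
        assert result.partners["mirror"] == "partner"

    def test_classification_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(31)
        profiles = {}
        pool = [f"s{i}" for i in range(30)]
        for p in range(12):
            reads = rng.choice(pool, size=rng.integers(1, 8), replace=False)
            profiles[f"p{p}"] = _profile(f"p{p}", {r: rng.random() for r in reads})
        ids = [f"p{p}" for p in range(12)]
        result = mc.classify_mr_only(ids, profiles)
        assert set(result.types) == set(ids)
        assert set(result.types.values()) <= {"Type-I", "Type-II", "Type-III"}


class TestSaturation:
    def test_nesting_is_exact(self):
        sets = [
            mc.ReadAlignmentSet(f"r{i}", (mc.CandidateAlignment(f"r{i}", "c", i, 36, "+"),))
            for i in range(500)
        ]
        rng = np.random.default_rng(1)
        sub = nested_subsamples(sets, [0.2, 0.4, 0.8], rng)
        ids = {f: {s.read_id for s in v} for f, v in sub.items()}
        assert ids[0.2] <= ids[0.4] <= ids[0.8]

    def test_bad_fraction_errors(self):
        with pytest.raises(ValueError, match="fraction"):
            nested_subsamples([], [1.5], np.random.default_rng(0))

    def test_full_fraction_recovers_gold(self):
        gold = [_peak(0, 400)]

        def pipeline(subset, mode):
            return gold

        curve = mc.saturation([], [], [0.5, 1.0], gold, pipeline, seed=0)
        assert (curve["recovery_pct"] == 100.0).all()
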