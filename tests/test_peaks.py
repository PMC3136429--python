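"""Conditional binomial test, NB-mixture fit, FDR control, peak merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import multichip as mc
from multichip.peaks import _bound_mask_cb, _bound_mask_posterior


def _bins(chip, inp, mapp=None, gc=None):
    n = len(chip)
    return pd.DataFrame(
        {
            "chrom": "c",
            "start": np.arange(n) * 200,
            "chip_fractional": np.asarray(chip, dtype=float),
            "chip_count": np.asarray(chip, dtype=int),
            "input_count": np.asarray(inp, dtype=int),
            "mappability": np.ones(n) if mapp is None else mapp,
            "gc": np.full(n, 0.5) if gc is None else gc,
        }
    )


class TestCBTest:
    def test_zero_chip_count_gives_p_one(self):
        res = mc.cb_test(_bins([0, 0, 5], [3, 0, 0]))
        assert res.pvalues[0] == 1.0 and res.pvalues[1] == 1.0

    def test_exact_tail_probability(self):
        # X=5, Y=0 at p0=0.5 -> P(Binom(5, .5) >= 5) = 2^-5
        bins = _bins([5, 0, 1, 0], [0, 1, 0, 0])
        res = mc.cb_test(bins)
        assert res.p0 == 0.5  # low-count bins: (0,1),(1,0),(0,0)
        assert res.pvalues[0] == pytest.approx(0.03125, abs=1e-12)

    def test_pvalues_match_direct_tail_sums(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 30, 300)
        y = rng.integers(0, 30, 300)
        res = mc.cb_test(_bins(x, y))
        for xi, yi, p in zip(x, y, res.pvalues):
            direct = sum(stats.binom.pmf(i, xi + yi, res.p0) for i in range(xi, xi + yi + 1))
            assert p == pytest.approx(direct, abs=1e-10)

    def test_degenerate_p0_falls_back_to_depth_ratio(self):
        bins = _bins([10, 20], [10, 20])
        with pytest.warns(UserWarning, match="depth ratio"):
            res = mc.cb_test(bins)
        assert res.p0 == 0.5

    def test_null_calibration(self):
        rng = np.random.default_rng(13)
        n = 10_000
        bins = _bins(rng.poisson(1.0, n), rng.poisson(1.0, n))
        res = mc.cb_test(bins)
        # discrete test is conservative: rejections at most nominal + CI slack
        assert (res.pvalues <= 0.05).mean() <= 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / n)


class TestBenjaminiHochberg:
    def test_matches_reference_step_up(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            p = rng.random(rng.integers(1, 200))
            mask = _bound_mask_cb(mc.CBTestResult(p, 0.5, 1), 0.1)
            # reference step-up: largest k with p_(k) <= k/m * alpha
            order = np.argsort(p)
            m = len(p)
            thresh = (np.arange(1, m + 1) / m) * 0.1
            below = np.nonzero(p[order] <= thresh)[0]
            expect = np.zeros(m, dtype=bool)
            if len(below):
                expect[order[: below.max() + 1]] = True
            assert (mask == expect).all()


class TestPosteriorFDR:
    def test_hand_worked_threshold(self):
        post = np.array([0.99, 0.98, 0.9, 0.5, 0.1])
        # background posteriors: .01, .02, .1, .5, .9; running means:
        # .01, .015, .0433, .1575, ... -> largest prefix with mean <= 0.05 is 3
        mask = _bound_mask_posterior(post, 0.05)
        assert mask.tolist() == [True, True, True, False, False]

    def test_no_bins_pass(self):
        assert not _bound_mask_posterior(np.array([0.5, 0.2]), 0.05).any()


class TestCallPeaks:
    def test_all_null_pvalues_give_no_peaks(self):
        bins = _bins([50] * 10, [50] * 10)
        res = mc.CBTestResult(np.ones(10), 0.5, 1)
        assert mc.call_peaks(res, bins, bin_size=200) == []

    def test_adjacent_bound_bins_merge(self):
        bins = _bins([100, 100, 0, 100], [1, 1, 1, 1])
        p = np.array([1e-9, 1e-9, 1.0, 1e-9])
        peaks = mc.call_peaks(mc.CBTestResult(p, 0.5, 1), bins, bin_size=200)
        assert len(peaks) == 2
        assert (peaks[0].start, peaks[0].end) == (0, 400)
        assert peaks[0].n_bins == 2 and peaks[1].n_bins == 1

    def test_min_chip_count_filter(self):
        bins = _bins([29, 100], [0, 0])
        p = np.array([1e-9, 1e-9])
        peaks = mc.call_peaks(mc.CBTestResult(p, 0.5, 1), bins, bin_size=200)
        assert len(peaks) == 1 and peaks[0].start == 200

    def test_empty_bin_table(self):
        assert mc.call_peaks(mc.CBTestResult(np.array([]), 0.5, 1), _bins([], [])) == []

    def test_peak_fields(self):
        bins = _bins([40, 60], [10, 10])
        p = np.array([1e-9, 1e-12])
        (peak,) = mc.call_peaks(mc.CBTestResult(p, 0.5, 1), bins, bin_size=200)
        assert peak.summit == 200  # bin with larger chip count
        assert peak.chip_sum == 100 and peak.input_sum == 20
        assert peak.score == 1e-12
        ratio = 100 / 20
        expect = np.mean([np.log2(41 / (10 * ratio + 1)), np.log2(61 / (10 * ratio + 1))])
        assert peak.avg_log2_enrichment == pytest.approx(expect)


class TestNBMixture:
    def test_background_only_collapses_mixture(self):
        bins, _ = mc.simulate_bin_counts(n_bins=20_000, bound_fraction=0.0, seed=3)
        fit = mc.fit_nb_mixture(bins)
        assert fit.pi_bound <= 0.01
        assert (fit.posterior <= 0.5).mean() >= 0.99

    def test_spiked_bins_get_high_posterior(self):
        bins, _ = mc.simulate_bin_counts(n_bins=20_000, bound_fraction=0.0, seed=5)
        rng = np.random.default_rng(6)
        spiked = rng.random(len(bins)) < 0.05
        mu = bins["chip_count"].to_numpy().astype(float).mean()
        counts = bins["chip_count"].to_numpy().copy()
        counts[spiked] = rng.poisson(20.0 * np.maximum(counts[spiked], mu / 2))
        bins = bins.assign(chip_count=counts, chip_fractional=counts.astype(float))
        fit = mc.fit_nb_mixture(bins)
        assert np.median(fit.posterior[spiked]) > 0.95

    def test_mappability_coefficient_recovery(self):
        bins, _ = mc.simulate_bin_counts(n_bins=50_000, mappability_coef=3.0, seed=7)
        fit = mc.fit_nb_mixture(bins)
        assert abs(fit.coefficients["mappability"] - 3.0) / 3.0 < 0.10

    def test_small_table_warns(self):
        bins, _ = mc.simulate_bin_counts(n_bins=500, seed=1)
        with pytest.warns(UserWarning, match="1000 bins"):
            mc.fit_nb_mixture(bins, max_iter=3)


@pytest.fixture(scope="module")
def bg_fit():
    bins, _ = mc.simulate_bin_counts(n_bins=30_000, bound_fraction=0.0, seed=9)
    return bins, mc.fit_nb_mixture(bins)


class TestGOF:
    def test_expected_frequencies_normalize(self, bg_fit):
        bins, fit = bg_fit
        table = mc.gof_summary(fit, bins)
        assert table["expected"].sum() == pytest.approx(len(bins), abs=1.0)
        assert (table["count"].to_numpy() == np.arange(len(table))).all()

    def test_background_fit_matches_observed_frequencies(self, bg_fit):
        bins, fit = bg_fit
        table = mc.gof_summary(fit, bins)
        common = table[table["observed"] >= 100]
        dev = np.abs(np.log10(common["observed"]) - np.log10(common["expected"]))
        assert dev.max() < 0.2


def test_peakcall_params_validation():
    with pytest.raises(ValueError):
        mc.PeakCallParams(fdr=0.0)
    with pytest.raises(ValueError):
        mc.PeakCallParams(method="macs")
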