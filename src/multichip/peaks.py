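"""Bin-level peak calling: conditional binomial test and NB-mixture model.

Two scoring routes over the same bin table:

* the conditional binomial (CB) test: under no binding and independent ChIP
  (X) and input (Y) counts, X | X+Y is Binomial(X+Y, p0).  The null
  proportion p0 is estimated from bins whose total count is at most a small
  threshold (default 1), where true binding is essentially absent.  Per-bin
  upper-tail p-values are corrected by Benjamini-Hochberg.

* a two-component mixture: background bins follow a negative binomial
  regression whose log mean is linear in mappability, a piecewise-linear GC
  B-spline (knots at the GC first and third quartiles), and log(1+input);
  bound bins add a shift constant (the minimum count observable in a bound
  region) plus a mixture of two negative binomials.  Fitting alternates a
  background regression on currently-background bins with responsibility
  updates (EM); the per-bin posterior probability of binding drives a
  direct posterior-based FDR (largest set of declared bins whose mean
  background posterior does not exceed the level).

Either route ends identically: bound bins below the minimum ChIP count are
dropped, the remainder merged into peaks over contiguous bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CBTestResult",
    "NBMixtureFit",
    "Peak",
    "PeakCallParams",
    "cb_test",
    "fit_nb_mixture",
    "call_peaks",
    "gof_summary",
]


@dataclass
class CBTestResult:
    pvalues: np.ndarray
    p0: float
    low_count_threshold: int


@dataclass
class PeakCallParams:
    fdr: float = 0.05
    min_chip_count: int = 30
    method: str = "cb"

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must be in (0, 1)")
        if self.method not in ("cb", "nbmix"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    score: float  # min p-value (CB) or max binding posterior (NB mixture)
    summit: int  # start of the member bin with the largest ChIP count
    chip_sum: int
    input_sum: int
    avg_log2_enrichment: float
    mean_mappability: float
    mean_gc: float
    n_bins: int

    def interval(self):
        from .io import Interval

        return Interval(self.chrom, self.start, self.end, "peak")

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def cb_test(bins: pd.DataFrame, low_count_threshold: int = 1) -> CBTestResult:
    """Conditional binomial upper-tail p-values for every bin.

    p0 is the ChIP share of the total counts among bins with
    X + Y <= low_count_threshold; if no such bins exist (or the estimate is
    degenerate) the global depth ratio is used with a warning.
    """
    x = bins["chip_count"].to_numpy()
    y = bins["input_count"].to_numpy()
    total = x + y
    low = total <= low_count_threshold
    cx, cy = x[low].sum(), y[low].sum()
    if cx + cy == 0 or cx == 0 or cy == 0:
        warnings.warn(
            "degenerate low-count p0 estimate; falling back to global depth ratio",
            stacklevel=2,
        )
        cx, cy = x.sum(), y.sum()
    p0 = cx / (cx + cy)
    # P(Binom(X+Y, p0) >= X); sf(X-1) so that X = 0 gives p = 1
    pvalues = stats.binom.sf(x - 1, total, p0)
    return CBTestResult(pvalues=pvalues, p0=float(p0), low_count_threshold=low_count_threshold)


@dataclass
class NBMixtureFit:
    coefficients: dict[str, float]
    dispersion: float
    pi_bound: float
    signal_means: tuple[float, float]
    signal_sizes: tuple[float, float]
    signal_mix: float
    shift: int
    posterior: np.ndarray  # per-bin P(bound | data)
    gc_knots: tuple[float, float]
    converged: bool
    n_iter: int
    mu_background: np.ndarray = field(repr=False, default=None)


def _design(bins: pd.DataFrame, knots: tuple[float, float]) -> np.ndarray:
    gc = bins["gc"].to_numpy()
    return np.column_stack(
        [
            np.ones(len(bins)),
            bins["mappability"].to_numpy(),
            gc,
            np.maximum(gc - knots[0], 0.0),
            np.maximum(gc - knots[1], 0.0),
            np.log1p(bins["input_count"].to_numpy()),
        ]
    )


_COEF_NAMES = ["intercept", "mappability", "gc", "gc_knot1", "gc_knot2", "log_input"]


def _nb_pmf(x: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    size = 1.0 / alpha
    return stats.nbinom.pmf(x, size, size / (size + mu))


def _fit_signal(
    s: np.ndarray,
    resp: np.ndarray,
    init_means: tuple[float, float],
    n_iter: int = 15,
) -> tuple[tuple[float, float], tuple[float, float], float]:
    """Weighted two-component NB mixture by inner EM with moment updates."""
    means = list(init_means)
    sizes = [2.0, 2.0]
    mix = 0.5
    for _ in range(n_iter):
        f0 = mix * _nb_pmf(s, np.full_like(s, means[0], dtype=float), 1.0 / sizes[0])
        f1 = (1 - mix) * _nb_pmf(s, np.full_like(s, means[1], dtype=float), 1.0 / sizes[1])
        tot = f0 + f1
        tot[tot == 0] = 1e-300
        r0 = f0 / tot
        for c, rc in enumerate((r0, 1.0 - r0)):
            wsum = np.sum(resp * rc)
            if wsum < 1e-8:
                continue
            m = np.sum(resp * rc * s) / wsum
            v = np.sum(resp * rc * (s - m) ** 2) / wsum
            means[c] = max(m, 1e-3)
            sizes[c] = float(np.clip(m**2 / max(v - m, 1e-6), 0.05, 1e4))
        wall = np.sum(resp)
        mix = float(np.clip(np.sum(resp * r0) / max(wall, 1e-8), 0.01, 0.99))
    return (means[0], means[1]), (sizes[0], sizes[1]), mix


def fit_nb_mixture(
    bins: pd.DataFrame,
    shift: int = 3,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> NBMixtureFit:
    """Fit the background/signal mixture by EM; deterministic initialization.

    Initialization fits the background regression on all bins and seeds the
    bound responsibilities from large Pearson residuals; signal components
    start at 5x and 20x the mean background level.  Returns the fit with a
    warning flag if EM did not converge within ``max_iter``.
    """
    if len(bins) < 1000:
        warnings.warn("fewer than 1000 bins; mixture fit may be unstable", stacklevel=2)
    x = bins["chip_count"].to_numpy().astype(float)
    gc = bins["gc"].to_numpy()
    knots = tuple(np.quantile(gc, [0.25, 0.75]))
    design = _design(bins, knots)

    alpha = 0.1
    glm = sm.GLM(x, design, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
    mu = glm.mu
    pearson = (x - mu) / np.sqrt(mu * (1 + alpha * mu))
    resp = (pearson > 3.0).astype(float)
    pi = float(np.clip(resp.mean(), 1e-4, 0.5))

    signal_means = (5.0 * mu.mean(), 20.0 * mu.mean())
    signal_sizes = (2.0, 2.0)
    signal_mix = 0.5
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        bg = resp < 0.5
        if bg.sum() < design.shape[1] + 2:
            break
        glm = sm.GLM(
            x[bg], design[bg], family=sm.families.NegativeBinomial(alpha=alpha)
        ).fit()
        mu = np.exp(design @ glm.params)
        # dispersion by Pearson moment matching on background bins
        resid2 = (x[bg] - mu[bg]) ** 2
        alpha_new = np.mean((resid2 - mu[bg]) / np.maximum(mu[bg] ** 2, 1e-8))
        alpha = float(np.clip(alpha_new, 1e-4, 10.0))

        s = x - shift
        sig_ok = s >= 0
        if resp[sig_ok].sum() > 1:
            signal_means, signal_sizes, signal_mix = _fit_signal(
                s[sig_ok], resp[sig_ok], signal_means
            )

        f_bg = _nb_pmf(x, mu, alpha)
        f_sig = np.zeros_like(x)
        m0, m1 = signal_means
        r0, r1 = signal_sizes
        f_sig[sig_ok] = signal_mix * _nb_pmf(
            s[sig_ok], np.full(sig_ok.sum(), m0), 1.0 / r0
        ) + (1 - signal_mix) * _nb_pmf(s[sig_ok], np.full(sig_ok.sum(), m1), 1.0 / r1)
        denom = pi * f_sig + (1 - pi) * f_bg
        denom[denom == 0] = 1e-300
        new_resp = pi * f_sig / denom
        delta = float(np.mean(np.abs(new_resp - resp)))
        resp = new_resp
        pi = float(np.clip(resp.mean(), 1e-6, 0.5))
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"NB mixture EM did not converge in {max_iter} iterations", stacklevel=2)
    return NBMixtureFit(
        coefficients=dict(zip(_COEF_NAMES, glm.params)),
        dispersion=alpha,
        pi_bound=pi,
        signal_means=tuple(signal_means),
        signal_sizes=tuple(signal_sizes),
        signal_mix=signal_mix,
        shift=shift,
        posterior=resp,
        gc_knots=knots,
        converged=converged,
        n_iter=it,
        mu_background=mu,
    )


def _bound_mask_cb(result: CBTestResult, fdr: float) -> np.ndarray:
    if len(result.pvalues) == 0:
        return np.zeros(0, dtype=bool)
    rejected, *_ = multipletests(result.pvalues, alpha=fdr, method="fdr_bh")
    return rejected


def _bound_mask_posterior(posterior: np.ndarray, fdr: float) -> np.ndarray:
    """Largest declared set whose running mean background posterior <= fdr."""
    bg = 1.0 - posterior
    order = np.argsort(bg, kind="stable")
    running = np.cumsum(bg[order]) / np.arange(1, len(bg) + 1)
    k = int(np.max(np.nonzero(running <= fdr)[0]) + 1) if np.any(running <= fdr) else 0
    mask = np.zeros(len(bg), dtype=bool)
    mask[order[:k]] = True
    return mask


def call_peaks(
    scores: CBTestResult | NBMixtureFit,
    bins: pd.DataFrame,
    params: PeakCallParams | None = None,
    bin_size: int | None = None,
) -> list[Peak]:
    """FDR-threshold bins, drop low-count bins, and merge contiguous runs.

    Bound bins with ChIP count below ``params.min_chip_count`` are removed
    before merging; adjacent bound bins (same chromosome, consecutive
    tiling) become one peak.
    """
    params = params or PeakCallParams()
    if len(bins) == 0:
        return []
    if bin_size is None:
        starts = np.sort(bins["start"].unique())
        bin_size = int(np.min(np.diff(starts))) if len(starts) > 1 else 200

    if isinstance(scores, CBTestResult):
        bound = _bound_mask_cb(scores, params.fdr)
        strength = -np.log10(np.maximum(scores.pvalues, 1e-300))
        score_vec = scores.pvalues
        score_of = min
    else:
        bound = _bound_mask_posterior(scores.posterior, params.fdr)
        score_vec = scores.posterior
        score_of = max
    bound = bound & (bins["chip_count"].to_numpy() >= params.min_chip_count)
    bound = bound & (bins["chip_count"].to_numpy() > 0)

    total_chip = max(int(bins["chip_count"].sum()), 1)
    total_input = max(int(bins["input_count"].sum()), 1)
    ratio = total_chip / total_input  # scale input to ChIP depth

    peaks: list[Peak] = []
    idx = np.flatnonzero(bound)
    if len(idx) == 0:
        return peaks
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    run: list[int] = [idx[0]]
    for i in idx[1:]:
        prev = run[-1]
        if chroms[i] == chroms[prev] and starts[i] == starts[prev] + bin_size:
            run.append(i)
        else:
            peaks.append(_make_peak(run, bins, score_vec, score_of, bin_size, ratio))
            run = [i]
    peaks.append(_make_peak(run, bins, score_vec, score_of, bin_size, ratio))
    return peaks


def _make_peak(run, bins, score_vec, score_of, bin_size, depth_ratio) -> Peak:
    sub = bins.iloc[run]
    chip = sub["chip_count"].to_numpy()
    inp = sub["input_count"].to_numpy()
    # depth-scaled per-bin enrichment with pseudocount 1
    enr = np.log2((chip + 1.0) / (inp * depth_ratio + 1.0))
    summit_row = run[int(np.argmax(chip))]
    return Peak(
        chrom=str(sub["chrom"].iloc[0]),
        start=int(sub["start"].iloc[0]),
        end=int(sub["start"].iloc[-1]) + bin_size,
        score=float(score_of(score_vec[i] for i in run)),
        summit=int(bins["start"].iloc[summit_row]),
        chip_sum=int(chip.sum()),
        input_sum=int(inp.sum()),
        avg_log2_enrichment=float(enr.mean()),
        mean_mappability=float(sub["mappability"].mean()),
        mean_gc=float(sub["gc"].mean()),
        n_bins=len(run),
    )


def write_peaks(peaks, path: str) -> None:
    """Write peaks as BED6+ (name, score, '.', enrichment, mappability, gc, summit, chip, input)."""
    with open(path, "w") as out:
        for i, p in enumerate(peaks):
            out.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{p.score:.6g}\t.\t"
                f"{p.avg_log2_enrichment:.4f}\t{p.mean_mappability:.4f}\t{p.mean_gc:.4f}\t"
                f"{p.summit}\t{p.chip_sum}\t{p.input_sum}\n"
            )


def read_peaks(path: str) -> list[Peak]:
    peaks = []
    with open(path) as handle:
        for line in handle:
            f = line.rstrip("\n").split("\t")
            peaks.append(
                Peak(
                    chrom=f[0], start=int(f[1]), end=int(f[2]), score=float(f[4]),
                    summit=int(f[9]), chip_sum=int(f[10]), input_sum=int(f[11]),
                    avg_log2_enrichment=float(f[6]), mean_mappability=float(f[7]),
                    mean_gc=float(f[8]), n_bins=(int(f[2]) - int(f[1])) // 200,
                )
            )
    return peaks


def gof_summary(fit: NBMixtureFit, bins: pd.DataFrame, max_count: int | None = None) -> pd.DataFrame:
    """Observed vs model-expected frequency of each ChIP count value.

    Expected frequency of count c sums, over bins, the fitted marginal
    (1-pi) * NB_background(c | bin) + pi * signal(c); expected frequencies
    total the number of bins up to truncation of the count range.
    """
    x = bins["chip_count"].to_numpy()
    mu = fit.mu_background
    top = int(x.max()) if max_count is None else max_count
    counts = np.arange(top + 1)
    observed = np.bincount(x, minlength=top + 1)[: top + 1]
    m0, m1 = fit.signal_means
    r0, r1 = fit.signal_sizes
    expected = np.empty(top + 1)
    for c in counts:
        f_bg = _nb_pmf(c, mu, fit.dispersion)
        if c >= fit.shift:
            f_sig = fit.signal_mix * _nb_pmf(c - fit.shift, m0, 1.0 / r0) + (
                1 - fit.signal_mix
            ) * _nb_pmf(c - fit.shift, m1, 1.0 / r1)
        else:
            f_sig = 0.0
        expected[c] = np.sum((1 - fit.pi_bound) * f_bg + fit.pi_bound * f_sig)
    return pd.DataFrame({"count": counts, "observed": observed, "expected": expected})
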