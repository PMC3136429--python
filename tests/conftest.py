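import numpy as np
import pytest

import multichip as mc

BENCH_SEED = 11


@pytest.fixture(scope="session")
def bench():
    """Standard 220 kb benchmark: one exact 20 kb duplication, 20 planted peaks."""
    return mc.benchmark_dataset(seed=BENCH_SEED)


@pytest.fixture(scope="session")
def covariates(bench):
    return mc.covariate_bins(bench.genome, bench.read_length)


@pytest.fixture(scope="session")
def pipelines(bench, covariates):
    """Full UR and MR conditional-binomial pipelines on the benchmark."""
    mapp, gc = covariates
    out = {}
    for mode in ("UR", "MR"):
        peaks, bins, chip_w, input_w = mc.run_peak_calling(
            bench.chip_sets,
            bench.input_sets,
            bench.chrom_lengths,
            mapp,
            gc,
            mode=mode,
            method="cb",
        )
        out[mode] = {"peaks": peaks, "bins": bins, "chip_weights": chip_w,
                     "input_weights": input_w}
    return out


def recovery_pct(called, planted):
    """Percentage of planted peaks overlapped (>= 1 bp) by called peaks."""
    if not planted:
        return float("nan")
    hits = sum(
        1
        for p in planted
        if any(c.chrom == p.chrom and c.start < p.end and p.start < c.end for c in called)
    )
    return 100.0 * hits / len(planted)


@pytest.fixture(scope="session")
def small_genome():
    """5 kb random genome with a 600 bp exact internal duplication."""
    spec = mc.SyntheticGenomeSpec(
        chrom_lengths={"chrA": 5000},
        duplications=[mc.Duplication("chrA", 1000, 1600, "chrA", 3000, 1.0)],
        seed=7,
    )
    genome, blocks = mc.simulate_genome(spec)
    return genome, blocks
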