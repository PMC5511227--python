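"""Shared fixtures: a small planted benchmark run reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from chlamirna import calling, synthetic

BENCHMARK_SEED = 11


@pytest.fixture(scope="session")
def benchmark():
    """Planted genome + truth + one simulated library + calls, fixed seed."""
    genome, truth = synthetic.benchmark_truth(
        rng_seed=BENCHMARK_SEED, libraries=("TAP",)
    )
    sims = synthetic.simulate_reads(
        truth,
        genome,
        {"TAP": 300_000},
        background_fraction=0.90,
        rng_seed=BENCHMARK_SEED,
    )
    calls, clusters = calling.call_library(sims["TAP"].aligned, genome)
    return {
        "genome": genome,
        "truth": truth,
        "library": sims["TAP"],
        "calls": calls,
        "clusters": clusters,
    }


@pytest.fixture(scope="session")
def calls_by_precursor(benchmark) -> dict[str, object]:
    """Map each planted precursor id to its (unique) overlapping call."""
    truth = benchmark["truth"]
    out: dict[str, list] = {}
    for call, cluster in zip(benchmark["calls"], benchmark["clusters"]):
        for pid, (chrom, ps, pe, _strand) in truth.placements.items():
            if cluster.chrom == chrom and cluster.span[0] < pe and ps < cluster.span[1]:
                out.setdefault(pid, []).append(call)
    assert all(len(v) == 1 for v in out.values()), "ambiguous cluster/truth matching"
    return {pid: v[0] for pid, v in out.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
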