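import numpy as np
import pytest

import peakbench as pb


@pytest.fixture
def iv():
    """Interval factory on a fixed test chromosome."""

    def make(start, end, chrom="chrT"):
        return pb.GenomicInterval(chrom, start, end)

    return make


@pytest.fixture(scope="session")
def tiny_config():
    """A small, fast benchmark configuration used by I/O and CLI tests."""
    return pb.SimulationConfig(
        n_samples=4, n_cell_types=2, n_windows=4, window_length=3000,
        peak_width_range=(60, 300), seed=11,
    )


@pytest.fixture(scope="session")
def tiny_benchmark(tiny_config):
    return pb.simulate_benchmark(tiny_config)


@pytest.fixture(scope="session")
def default_benchmark():
    """The default study conditions: mu0=5, mu1=30, 20 samples, 8 windows."""
    return pb.simulate_benchmark(pb.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_call_set(default_benchmark):
    return pb.build_call_set(default_benchmark.coverage)
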