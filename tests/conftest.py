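import numpy as np
import pytest
from hypothesis import settings

from spontact import (GCaMPKernel, SimulationConfig, TraceMatrix,
                      delta_f_over_f0, generate_benchmark)

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced benchmark recording (60 neurons) for unit-level tests."""
    config = SimulationConfig(n_neurons=60, seed=424242)
    traces, labels, truth = generate_benchmark(config)
    return traces, labels, truth, config


@pytest.fixture(scope="session")
def small_benchmark_dff(small_benchmark):
    traces, labels, truth, config = small_benchmark
    return delta_f_over_f0(traces), labels, truth, config


@pytest.fixture
def flat_traces():
    """A constant-valued normalized matrix: 3 neurons × 400 frames."""
    return TraceMatrix(np.zeros((3, 400)), sampling_rate=3.65,
                       normalized=True)


def make_traces(values, rate=3.65, normalized=True):
    return TraceMatrix(np.atleast_2d(np.asarray(values, dtype=float)),
                       sampling_rate=rate, normalized=normalized)


@pytest.fixture(scope="session")
def kernel():
    return GCaMPKernel()
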