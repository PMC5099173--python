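import numpy as np
import pytest

from sideobsp import generate_benchmark, generate_physio_scenario, side_obsp


@pytest.fixture(scope="session")
def bench_clean():
    """Noise-free, uncorrelated, uncontaminated benchmark (exact MA truth)."""
    return generate_benchmark(101, rho=0.0, snr_db=None, output_contamination=0.0)


@pytest.fixture(scope="session")
def bench_corr_clean():
    """Noise-free benchmark with rho = 0.5 correlated inputs."""
    return generate_benchmark(102, rho=0.5, snr_db=None, output_contamination=0.0)


@pytest.fixture(scope="session")
def bench_noisy():
    """Full study conditions: rho = 0.5, SNR 4 dB, contaminated output."""
    return generate_benchmark(103)


@pytest.fixture(scope="session")
def decomp_noisy(bench_noisy):
    return side_obsp(bench_noisy.sigset, p=50, gamma=0.0)


@pytest.fixture(scope="session")
def physio():
    return generate_physio_scenario(104)


def rand_partition(rng, n_rows, p_k, p_rest, correlated=False):
    """Random full-rank block pair, optionally sharing a common component."""
    A_k = rng.standard_normal((n_rows, p_k))
    A_rest = rng.standard_normal((n_rows, p_rest))
    if correlated:
        shared = rng.standard_normal((n_rows, 1))
        A_k = A_k + shared
        A_rest = A_rest + shared
    return A_k, A_rest
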