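import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from readtint import IndexParams, SimulationConfig, simulate_genome, simulate_reads

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_params() -> IndexParams:
    """Desk-toy parameters: short k-mers, tiny filter."""
    return IndexParams(k=9, m=4, min_abundance=1, max_abundance=10**6,
                       filter_log2_size=16)


@pytest.fixture(scope="session")
def small_simulation():
    """A 20 kb genome at 10X with 1% errors; shared across modules."""
    config = SimulationConfig(
        genome_length=20_000,
        coverage=10.0,
        read_length_mean=2_000,
        read_length_spread=300,
        error_rate=0.01,
        rng_seed=7,
    )
    genome = simulate_genome(config)
    reads, origins = simulate_reads(genome, config)
    return config, genome, reads, origins
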