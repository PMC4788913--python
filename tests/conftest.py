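"""Shared fixtures: small simulated worlds reused across test modules."""

import pytest

from capemeth.simulate import SimulationConfig, build_world, simulate_count_table


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, genome_length=60_000, n_genes=10,
                            n_control_sites=3_000)


@pytest.fixture(scope="session")
def small_world(small_config):
    return build_world(small_config)


@pytest.fixture(scope="session")
def small_tables(small_world):
    """(counts, control) for both modes of the small world."""
    return {
        mode: simulate_count_table(small_world, mode)
        for mode in ("fertilized", "thelytokous")
    }
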