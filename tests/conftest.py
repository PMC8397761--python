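import numpy as np
import pytest

from rhizodiel import (
    SimulationConfig,
    absolute_abundance,
    normalize_counts,
    simulate_community,
)


@pytest.fixture(scope="session")
def default_rhizosphere_sim():
    """Reference experiment: default design, rhizosphere only, seed 1."""
    cfg = SimulationConfig(seed=1, compartments=("rhizosphere",))
    counts, meta, qpcr, truth = simulate_community(cfg)
    return cfg, counts, meta, qpcr, truth


@pytest.fixture(scope="session")
def normalized_rhizosphere(default_rhizosphere_sim):
    _, counts, meta, _, _ = default_rhizosphere_sim
    return normalize_counts(counts), meta


@pytest.fixture(scope="session")
def absolute_rhizosphere(default_rhizosphere_sim):
    _, counts, meta, qpcr, _ = default_rhizosphere_sim
    return absolute_abundance(counts, qpcr), meta


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
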