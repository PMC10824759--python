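import numpy as np
import pytest

from pausekit.simulate import SimulationParams, simulate_annotation


@pytest.fixture(scope="session")
def small_params():
    """A reduced genome that keeps per-test simulation under a second."""
    return SimulationParams(n_genes=400, genome_len=15_000_000)


@pytest.fixture(scope="session")
def small_truth(small_params):
    models, truth = simulate_annotation(small_params, seed=11)
    return models, truth


@pytest.fixture(scope="session")
def default_truth():
    """Full-size study conditions (2000 genes); built once per session."""
    models, truth = simulate_annotation(seed=1)
    return models, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
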