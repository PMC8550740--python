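import pytest

from coidiv import simulate
from coidiv.datasets import load_uganda_counts


@pytest.fixture(scope="session")
def panel_and_refs():
    """Six-species reference panel at ~8% pairwise divergence."""
    cfg = simulate.SimulationConfig(seed=11, n_species=6)
    return simulate.simulate_panel(cfg)


@pytest.fixture(scope="session")
def panel(panel_and_refs):
    return panel_and_refs[0]


@pytest.fixture(scope="session")
def uganda_counts():
    return load_uganda_counts()


@pytest.fixture(scope="session")
def seed_orf():
    return simulate.load_seed_orf()
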