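import pytest

from coevonet.cma import CmaConfig, compute_cma_matrix
from coevonet.msa import CorePositions, Msa, derive_core_positions
from coevonet.simfam import PlantedNetwork, SimConfig, simulate_family


@pytest.fixture
def toy_msa():
    """Four short sequences with a gap column and an offset sequence."""
    return Msa(
        ids=["human", "mouse", "yeast", "fly"],
        rows=["M-KHA", "MAKHC", "M-KHA", "MAK-C"],
        offsets={"mouse": 21},
    )


@pytest.fixture
def toy_core(toy_msa):
    return derive_core_positions(toy_msa, max_gap_frac=0.3)


@pytest.fixture(scope="session")
def sim_family():
    """A moderate planted-network family shared by the slower tests."""
    config = SimConfig(
        n_sequences=2000,
        n_positions=60,
        networks=(PlantedNetwork(tuple(range(4, 60, 5)), "enantioselectivity"),),
        p_cons=0.9,
        gap_rate=0.05,
        seed=42,
    )
    msa, truth = simulate_family(config)
    core = derive_core_positions(msa)
    return msa, core, truth


@pytest.fixture(scope="session")
def sim_matrix(sim_family):
    msa, core, truth = sim_family
    return compute_cma_matrix(msa, core, CmaConfig(method="sca"))
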