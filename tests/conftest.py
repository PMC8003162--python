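import numpy as np
import pytest

from glucanbind import (
    LigandModel,
    ReceptorModel,
    SimulationSettings,
    build_toy_system,
    simulate,
)


@pytest.fixture(scope="session")
def receptor():
    return ReceptorModel()


@pytest.fixture(scope="session")
def monomer_ligand():
    return LigandModel(n_monomers=1)


@pytest.fixture(scope="session")
def chain_ligand():
    return LigandModel(n_monomers=5)


@pytest.fixture(scope="session")
def short_traj(receptor, chain_ligand):
    """A short 2-chain trajectory shared by io/density/event tests."""
    box = (45.0, 45.0, 45.0)
    _, pos0 = build_toy_system(receptor, chain_ligand, 2, box, seed=11)
    settings = SimulationSettings(n_steps=20_000, box_lengths=box, seed=11, save_stride=100)
    return simulate(receptor, chain_ligand, pos0, settings)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
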