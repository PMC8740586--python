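import numpy as np
import pytest

from escrtsim.params import (AdhesionParams, FilamentParams, HelixSpec,
                             MembraneParams, ProtocolSchedule, SimConfig)


@pytest.fixture(scope="session")
def membrane_params():
    return MembraneParams()


@pytest.fixture(scope="session")
def adhesion_params():
    return AdhesionParams()


@pytest.fixture(scope="session")
def filament_params():
    return FilamentParams()


@pytest.fixture
def small_helix():
    """A desk-sized helix spec used across geometry tests."""
    return HelixSpec(radius=10.0, n_turns=2.0, n_subunits=60,
                     axial_width=6.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest legal simulation cell, for integration tests."""
    return SimConfig(
        vesicle_radius=8.0,
        helix=HelixSpec(radius=8.0, n_turns=2.0, n_subunits=40,
                        axial_width=6.5),
        relax_time=5.0,
        grace_time=20.0,
    )


@pytest.fixture(scope="session")
def null_schedule():
    return ProtocolSchedule(mode="instantaneous", target_ratio=1.0,
                            m_dis=0, rng_seed=0)
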