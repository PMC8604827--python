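import pytest

from iapbpk import (
    DoseEvent,
    SimulationSettings,
    healthy_knee_preset,
    mtx_pk_preset,
    mtx_preset,
    ra_knee_preset,
    simulate,
)


@pytest.fixture(scope="session")
def mtx():
    return mtx_preset()


@pytest.fixture(scope="session")
def pk70():
    return mtx_pk_preset(70.0)


@pytest.fixture(scope="session")
def ia_dose():
    return DoseEvent(route="IA", amount=5.0, vehicle_volume=2.0)


@pytest.fixture(scope="session")
def healthy_result(mtx, pk70, ia_dose):
    """Case-study run with the healthy knee (shared across tests)."""
    return simulate(healthy_knee_preset(), mtx, pk70, ia_dose, SimulationSettings())


@pytest.fixture(scope="session")
def ra_result(mtx, pk70, ia_dose):
    """Case-study run with the RA knee (shared across tests)."""
    return simulate(ra_knee_preset(), mtx, pk70, ia_dose, SimulationSettings())
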