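import numpy as np
import pytest

from golgiph import kinetics
from golgiph.electrochem import MembraneConditions


@pytest.fixture(scope="session")
def body_temp_conditions():
    return MembraneConditions(temperature=310.15, ph_lumen=6.0, ph_cytosol=7.0)


@pytest.fixture(scope="session")
def control_model():
    """(compartment, params, cytosol bath) for the control preset."""
    return kinetics.load_preset("cos7_control")


@pytest.fixture(scope="session")
def ae2plus_params():
    return kinetics.load_preset("cos7_ae2plus")[1]


@pytest.fixture(scope="session")
def sw48_params():
    return kinetics.load_preset("sw48")[1]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def acidify_protocol(bath_kind: str, t_atp: float = 1.0) -> kinetics.Protocol:
    bath = kinetics.permeabilized_bath(bath_kind)
    return kinetics.Protocol([(0.0, "permeabilize", bath), (t_atp, "add_atp", 10.0)])


def acidify_then_cma_protocol(
    acid_bath: str, leak_bath: str, t_switch: float
) -> kinetics.Protocol:
    """Acidify under one bath, then switch to an inhibitor/ATP-free bath."""
    import copy

    b2 = copy.deepcopy(kinetics.permeabilized_bath(leak_bath))
    b2.cma_present = True
    b2.atp_mM = 0.0
    return kinetics.Protocol(
        [
            (0.0, "permeabilize", kinetics.permeabilized_bath(acid_bath)),
            (0.5, "add_atp", 10.0),
            (t_switch, "set_bath", b2),
        ]
    )
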