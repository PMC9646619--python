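import numpy as np
import pytest

from wheatphys import calibration as cal
from wheatphys.constants import DiscriminationConstants
from wheatphys.isotope import LeafState
from wheatphys.synthetic import ExperimentConfig

#: The five leaf temperatures of the thermal-response protocol.
FIVE_TEMPS = np.array([15.0, 20.0, 25.0, 30.0, 35.0])

#: The 8-step CO2 ladder of the A-Ci protocol.
CO2_STEPS = np.array([50.0, 100.0, 230.0, 330.0, 420.0, 650.0, 1200.0, 1800.0])


@pytest.fixture
def scout_params():
    return cal.cultivar_params("Scout")


@pytest.fixture
def yitpi_params():
    return cal.cultivar_params("Yitpi")


@pytest.fixture
def disc_consts():
    return DiscriminationConstants()


@pytest.fixture
def leaf_state():
    """Representative lit-leaf state for the gm estimator."""
    return LeafState(A=20.0, Rd=1.25, E=0.003, Ca=400.0, Ci=280.0,
                     GammaStar=42.75, gt_ac=0.4)


@pytest.fixture
def small_config():
    return ExperimentConfig(seed=42, n_per_cell=4)


@pytest.fixture
def noiseless_config():
    return ExperimentConfig(seed=42, n_per_cell=4, noise_cv_traits=0.0,
                            noise_cv_gas=0.0)
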