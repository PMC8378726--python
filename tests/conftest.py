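import numpy as np
import pytest

from lpvsup.cli_io import ToolkitConfig
from lpvsup.patient_model import plant_state_space
from lpvsup.smith_lft import augment_and_decompose, build_uncertainty_lft
from lpvsup.supervisor_sim import build_hysteresis
from lpvsup.synthesis import default_partition, partition_and_design

TAU0 = 35.0
H0 = 40.0
THETA_RANGE = (-9.5, -0.25)


@pytest.fixture(scope="session")
def bank():
    """The five-region controller bank of the blood-pressure design."""
    regions, results = partition_and_design(THETA_RANGE,
                                            initial_regions=default_partition(),
                                            tau0=TAU0, h0=H0)
    return results


@pytest.fixture(scope="session")
def smiths(bank):
    return [augment_and_decompose(
        build_uncertainty_lft(res.region, TAU0, H0)[0], dt=0.1)
        for res in bank]


@pytest.fixture(scope="session")
def logic(bank):
    return build_hysteresis([res.region for res in bank], 0.2)


@pytest.fixture(scope="session")
def plant_map():
    return lambda theta: plant_state_space(theta, TAU0)
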