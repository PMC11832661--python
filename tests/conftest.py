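import numpy as np
import pytest

from ssvb import (
    AcquisitionSchedule,
    TissueConstants,
    get_schedule,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def constants():
    return TissueConstants()


@pytest.fixture(scope="session")
def grey_schedule():
    return get_schedule("grey_paper")


@pytest.fixture(scope="session")
def hcp_schedule():
    return get_schedule("hcp_asl")


@pytest.fixture(scope="session")
def tiny_schedule():
    """A short 3-PLD schedule for fast unit tests."""
    return AcquisitionSchedule(label_duration=1.8,
                               plds=(0.25, 1.0, 1.75),
                               repeats=(2, 2, 2), name="tiny")


@pytest.fixture(scope="session")
def small_noisy_dataset(grey_schedule, constants):
    """3x3x3 grey-schedule dataset at moderate noise."""
    return simulate_dataset(grey_schedule, constants, grid_shape=(3, 3, 3),
                            true_cbf=60.0, true_att=1.5, noise_sd=20.0,
                            rng=123)


@pytest.fixture(scope="session")
def small_noiseless_dataset(grey_schedule, constants):
    return simulate_dataset(grey_schedule, constants, grid_shape=(3, 3, 3),
                            true_cbf=60.0, true_att=1.5, noise_sd=0.0,
                            rng=0)
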