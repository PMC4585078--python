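import warnings

import numpy as np
import pytest

from fourlink.geometry import LegState, make_default_cat_leg
from fourlink.synthetic import CohortSpec, generate_trial

warnings.filterwarnings("ignore", message="toe moved backward")


@pytest.fixture(scope="session")
def geometry():
    return make_default_cat_leg()


@pytest.fixture(scope="session")
def noiseless_trial(geometry):
    """One noiseless mid-range synthetic trial with its ground truth."""
    spec = CohortSpec(marker_noise_sd=0.0, emg_noise_sd=0.0, seed=3)
    rng = np.random.default_rng(3)
    return generate_trial(geometry, spec, 0.15, rng, trial_id="fixture-015")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_state(rng, vel_scale=5.0):
    return LegState(rng.uniform(-np.pi, np.pi, 4), rng.uniform(-vel_scale, vel_scale, 4))
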