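import numpy as np
import pytest

from pacseq import ControlProfile, lognormalize
from pacseq.synthetic_data import SimConfig, make_control_matrix


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    """Study-condition defaults used across the suite (seed fixed)."""
    return SimConfig(seed=2)


@pytest.fixture(scope="session")
def control_matrix(default_cfg):
    """A 2000-cell x 1000-gene synthetic control population (counts, true means)."""
    return make_control_matrix(default_cfg)


@pytest.fixture(scope="session")
def control_profile(control_matrix) -> ControlProfile:
    cm, _mu = control_matrix
    return ControlProfile.from_normalized(lognormalize(cm))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
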