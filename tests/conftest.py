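import numpy as np
import pytest

import phloempet as pp
from phloempet.model import PRIMARY_SHOOT_PARAMS


@pytest.fixture(scope="session")
def paper_params():
    """Mean primary-shoot transport parameters."""
    return PRIMARY_SHOOT_PARAMS


@pytest.fixture(scope="session")
def primary_geom():
    return pp.RoiGeometry.primary()


@pytest.fixture(scope="session")
def default_cfg():
    return pp.SyntheticConfig()


@pytest.fixture(scope="session")
def roi_set(default_cfg):
    """(noiseless, noisy, truth) for the default primary-shoot config."""
    return pp.generate_roi_set(default_cfg)


@pytest.fixture(scope="session")
def noiseless_tac(roi_set):
    return roi_set[0]


@pytest.fixture
def constant_input_tac():
    """24-frame table whose input column is constant at 1.5 MBq/mL."""
    t = pp.TacTable.default_grid()
    vals = np.zeros((24, 4))
    vals[:, 0] = 1.5
    return pp.TacTable(t, vals)
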