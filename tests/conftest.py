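import numpy as np
import pytest

import pulsema as pm


@pytest.fixture(scope="session")
def params_1dof():
    return pm.nominal_params(two_dof=False)


@pytest.fixture(scope="session")
def params_2dof():
    return pm.nominal_params(two_dof=True)


@pytest.fixture(scope="session")
def grid():
    return pm.TimeGrid(0.0, 12.0, 1e-3)


@pytest.fixture(scope="session")
def canonical_1dof_result():
    """Full forward run of the canonical wall-displacement scenario."""
    return pm.run_scenario(pm.preset("canonical_1dof"))


@pytest.fixture(scope="session")
def canonical_2dof_result():
    """Full forward run of the canonical pulsatile-pressure scenario."""
    return pm.run_scenario(pm.preset("canonical_2dof"))


@pytest.fixture(scope="session")
def analysis_window(grid):
    return grid.mask_after(2.0)


def rel_l2(a, b):
    return np.linalg.norm(a - b) / np.linalg.norm(b)
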