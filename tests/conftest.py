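import numpy as np
import pytest

import nemascreen as ns


@pytest.fixture(scope="session")
def small_library():
    """20 compounds, 6 planted actives, 4 chemotype clusters."""
    return ns.make_library(20, 0.3, 4, seed=11)


@pytest.fixture(scope="session")
def small_layouts(small_library):
    return ns.make_interplate_titration(small_library)


@pytest.fixture(scope="session")
def seven_point_concs():
    """Final in-well molar concentrations of the default 7-point design."""
    return 10e-3 / 5.0 ** np.arange(6, -1, -1) / 240.0
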