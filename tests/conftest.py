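import numpy as np
import pytest

import dnamelt as dm


@pytest.fixture(scope="session")
def params():
    return dm.ForceFieldParams.default()


@pytest.fixture(scope="session")
def seq11():
    return dm.study_sequences()["11bp"]


@pytest.fixture(scope="session")
def topo11(seq11, params):
    return dm.build_duplex(seq11, params)


@pytest.fixture(scope="session")
def minimized11(topo11, params):
    return dm.minimize(
        dm.initial_coordinates(topo11), topo11, params, n_steps=4000
    )
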