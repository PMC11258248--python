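import numpy as np
import pytest

from polyhop.geometry import lutein_like_topology


@pytest.fixture(scope="session")
def topology():
    return lutein_like_topology()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240129)
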