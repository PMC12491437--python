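import numpy as np
import pytest

from gpcrdimer.simulate import synthetic_protomer


@pytest.fixture(scope="session")
def probe():
    """Reference Cα helix used as the docking probe in pose tests."""
    return synthetic_protomer(n_residues=40)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
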