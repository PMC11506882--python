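import numpy as np
import pytest

from cstgat import CouplingSpec, TEParams


@pytest.fixture(scope="session")
def single_edge_spec() -> CouplingSpec:
    """Two channels, one directed edge 0 -> 1 with strength 0.6."""
    return CouplingSpec(n_channels=2, edges=((0, 1, 0.6),), ar_self=0.5, noise_sd=1.0, lag=1)


@pytest.fixture(scope="session")
def default_te_params() -> TEParams:
    return TEParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
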