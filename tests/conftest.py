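import numpy as np
import pytest

from chargedrods.potential import PotentialParams


@pytest.fixture()
def rng():
    return np.random.default_rng(20230206)


@pytest.fixture(scope="session")
def params50():
    """Paper-resolution potential at short screening length (cheap clusters)."""
    return PotentialParams(kappa_star=50.0, M=15, n_trunc=10)


@pytest.fixture(scope="session")
def params_small():
    """Coarse discretization for brute-force comparisons."""
    return PotentialParams(kappa_star=20.0, M=5, n_trunc=4)
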