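import numpy as np
import pytest

import ramansort as rs


@pytest.fixture(scope="session")
def polymer_basis() -> rs.SpectralBasis:
    return rs.default_polymer_basis()


@pytest.fixture(scope="session")
def acq() -> rs.AcquisitionConfig:
    return rs.AcquisitionConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
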