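import numpy as np
import pytest

import oxmem


@pytest.fixture(scope="session")
def native():
    return oxmem.build_native_composition()


@pytest.fixture(scope="session")
def ferro(native):
    return oxmem.apply_ferroptosis_substitution(native, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
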