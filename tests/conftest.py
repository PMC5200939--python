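import numpy as np
import pytest

from tcrep.germline import builtin_toy_reference


@pytest.fixture(scope="session")
def toy_db():
    return builtin_toy_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
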