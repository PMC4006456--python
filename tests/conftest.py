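import numpy as np
import pytest


@pytest.fixture(autouse=True)
def _stable_numpy_errstate():
    with np.errstate(over="raise"):
        yield
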