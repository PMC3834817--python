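import numpy as np
import pytest

from visemech.params import MechParams


@pytest.fixture(scope="session")
def params() -> MechParams:
    return MechParams()


@pytest.fixture(autouse=True)
def _seed_numpy():
    # tests draw their own Generators; this guards any legacy global use
    np.random.seed(0)
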