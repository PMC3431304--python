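import numpy as np
import pytest

from symcoev.matrices import MasterMatrix
from symcoev.sampling import _draw_accepted


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def random_masters():
    """Twenty protection-constrained i.u.d. master matrices, fixed seed."""
    gen = np.random.default_rng(777)
    return [MasterMatrix(e) for e in _draw_accepted(gen, 20, "iud")]
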