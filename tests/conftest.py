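import numpy as np
import pytest

from grnevolve import ExpressionMatrix, RegInitConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def reg_cfg():
    return RegInitConfig()


def make_E(values, q0=None):
    """Build an ExpressionMatrix directly from a (n, m) array."""
    values = np.asarray(values, dtype=float)
    if q0 is None:
        q0 = np.zeros(values.shape[0])
        q0[0] = 1.0
    return ExpressionMatrix(values, np.asarray(q0, dtype=float))
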