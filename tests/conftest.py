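import numpy as np
import pytest

from lcmqsm.geometry import GridGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def geom16():
    return GridGeometry((16, 16, 16))


@pytest.fixture
def geom8():
    return GridGeometry((8, 8, 8))


def numeric_gradient(f, x, eps=1e-6):
    """Central finite-difference gradient of scalar f at array x."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


def relative_error(a, b):
    denom = max(np.max(np.abs(a)), np.max(np.abs(b)), 1e-300)
    return np.max(np.abs(a - b)) / denom
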