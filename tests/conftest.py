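import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240920)


def random_mask_pair(rng, shape, p_fg=0.3):
    """A probability map and a binary mask of matching shape."""
    p = rng.random(shape)
    g = (rng.random(shape) < p_fg).astype(np.int64)
    return p, g


def numerical_gradient(f, x, eps=1e-5):
    """Central-difference gradient of scalar f() with respect to array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
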