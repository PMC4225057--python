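import numpy as np
import pytest

import aucquad as aq


@pytest.fixture(scope="session")
def models():
    return {i: aq.get_model(i) for i in range(1, 6)}


@pytest.fixture(scope="session")
def boxes():
    return {i: aq.default_box(i) for i in range(1, 6)}


#: representative interior parameter vectors, one per model
INTERIOR_THETA = {
    1: np.array([1.2, 0.15]),
    2: np.array([0.9, 0.12]),
    3: np.array([1.0, 0.08, 1.05]),
    4: np.array([8.0, 0.5]),
    5: np.array([3.0, 0.55, 0.6]),
}


def central_diff(f, x, i, rel_step=1e-5):
    """Central finite difference of f (scalar or array valued) in x[i]."""
    h = rel_step * max(abs(x[i]), 1e-4)
    xp, xm = np.array(x, float), np.array(x, float)
    xp[i] += h
    xm[i] -= h
    return (np.asarray(f(xp)) - np.asarray(f(xm))) / (2.0 * h)


def assert_close_mixed(actual, expected, rtol, atol):
    """Relative comparison with an absolute floor for near-zero entries."""
    actual = np.asarray(actual, float)
    expected = np.asarray(expected, float)
    np.testing.assert_allclose(actual, expected, rtol=rtol, atol=atol)
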