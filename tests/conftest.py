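import numpy as np
import pytest

from cutabi.synthetic import build_hairpin, build_helix


@pytest.fixture(scope="session")
def ideal_helix():
    trace, labels = build_helix(10)
    return trace, labels


@pytest.fixture(scope="session")
def hairpin():
    trace, labels = build_hairpin(6)
    return trace, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
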