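import numpy as np
import pytest

from aptamd import synthetic_data as syn
from aptamd.energetics import EnergeticsConfig


@pytest.fixture(scope="session")
def toy():
    """Default rigid toy pocket complex."""
    return syn.build_toy_complex()


@pytest.fixture(scope="session")
def config():
    return EnergeticsConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
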