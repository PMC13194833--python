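import numpy as np
import pytest

from relconn.cohort import GroundTruthSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unidir_spec():
    """2-channel MVAR: channel 0 drives channel 1 at lag 1, no reverse."""
    return GroundTruthSpec(
        n_channels=2, mvar_order=1,
        coupling=[(0, 0, (0.5,)), (1, 1, (0.5,)), (0, 1, (0.4,))],
        seed=7)


def random_stable_coeffs(rng, n=4, p=2, radius=0.8):
    """Random lag stack scaled to a given companion spectral radius."""
    from relconn.cohort import companion_spectral_radius

    A = rng.standard_normal((p, n, n)) * 0.3
    r = companion_spectral_radius(A)
    return A * (radius / r) ** (1.0)  # approximate; verified below


@pytest.fixture
def stable_coeffs(rng):
    from relconn.cohort import companion_spectral_radius

    while True:
        A = random_stable_coeffs(rng)
        if companion_spectral_radius(A) < 0.95:
            return A
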