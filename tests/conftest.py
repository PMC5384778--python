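import numpy as np
import pytest

from dosewarp import make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One small noisy phantom shared by read-only tests."""
    return make_phantom(42, size=32, spacing=3.0, n_impulses=60)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250923)


def random_direction_matrix(rng) -> np.ndarray:
    """A random proper orthonormal 3x3 matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
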