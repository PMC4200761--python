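import warnings

import numpy as np
import pytest

from patchscreen.fixtures import FixtureSpec, make_complex_fixture

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_complex():
    """One small complementary complex shared by integration-level tests."""
    return make_complex_fixture(FixtureSpec(seed=11, n_atoms=16, cavity_radius=6.0))


@pytest.fixture(scope="session")
def cap_patch_points():
    """A spherical-cap point cloud (a patch-like surface sheet), radius 5 Å."""
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(400, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    return pts[pts[:, 2] > 0.3] * 5.0
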