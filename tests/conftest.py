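import numpy as np
import pytest

from conformscape import msm, synth


@pytest.fixture(scope="session")
def toy_bundle():
    return synth.make_toy_bundle(seed=11)


@pytest.fixture(scope="session")
def three_well_surface():
    return synth.make_cv_surface(synth.default_wells())


@pytest.fixture(scope="session")
def brownian_small(three_well_surface):
    """Short Brownian ensemble shared by the MSM unit tests."""
    cfg = synth.default_brownian_config(steps=8000, n_traj=5, seed=21)
    return synth.simulate_brownian(three_well_surface, cfg)


@pytest.fixture(scope="session")
def microstates_small(brownian_small):
    return msm.cluster_microstates(brownian_small.features, k=120, seed=21)


def random_rigid_motion(rng):
    """A uniformly random proper rotation and a random translation."""
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-50, 50, 3)
    return Q, t
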