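import numpy as np
import pytest

from bladderrad.phantom import PhantomParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six lesions (3 NMIBC / 3 MIBC), shared across read-only tests."""
    return generate_cohort(3, 3, "train", PhantomParams(), seed=11)


def make_small_phantom_params():
    """Small lesions that fit comfortably in a 48-px network input."""
    p = PhantomParams()
    p.nmibc.base_radius_mm = 5.0
    p.nmibc.radius_jitter = 0.15
    p.mibc.base_radius_mm = 6.5
    p.mibc.radius_jitter = 0.15
    p.max_inplane_extent_mm = 26.0
    return p


@pytest.fixture(scope="session")
def small_phantom_params():
    return make_small_phantom_params()


def random_blob_mask(rng, shape=(16, 24, 24), radius_range=(2.5, 5.0)):
    """Single random ellipsoidal blob fully inside the volume."""
    r = rng.uniform(*radius_range, size=3)
    margin = np.ceil(r).astype(int) + 1
    center = [rng.integers(m, s - m) for m, s in zip(margin, shape)]
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    d = (((zz - center[0]) / r[0]) ** 2 + ((yy - center[1]) / r[1]) ** 2
         + ((xx - center[2]) / r[2]) ** 2)
    return d <= 1.0
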