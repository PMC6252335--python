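import numpy as np
import pytest

from faceherit import default_design, make_template, simulate_cohort


@pytest.fixture(scope="session")
def template_5x5():
    return make_template((5, 5))


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort shared by IO / pipeline tests."""
    design = default_design(grid_shape=(5, 5), n_pairs=20, seed=7)
    return simulate_cohort(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_configuration(rng, k=12, scale=1.0):
    return scale * rng.normal(size=(k, 3))


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
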