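import numpy as np
import pytest

from manifoldmri import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """Small 4-class study: quick to render, same geometry as the default."""
    return syn.default_study(n_images=60, image_size=32, basis_seed=5,
                             sample_seed=9)


@pytest.fixture(scope="session")
def small_pixel_features(small_study):
    return syn.study_feature_matrix(small_study)


def random_spd(rng, d, scale=1.0):
    """Well-conditioned random SPD matrix."""
    A = rng.standard_normal((d, d))
    return scale * (A @ A.T / d + np.eye(d))
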