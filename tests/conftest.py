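import numpy as np
import pytest

from mitopop import simulate


@pytest.fixture(scope="session")
def scene():
    return simulate.SceneSpec()


@pytest.fixture(scope="session")
def noiseless_scene():
    return simulate.SceneSpec(noise_read_sd=0.0, photon_scale=0.0)


@pytest.fixture(scope="session")
def subject():
    return simulate.SubjectSpec(subject_id=1, pi_low=0.3)


@pytest.fixture(scope="session")
def tile_truth(scene, subject):
    return simulate.render_tile(scene, subject, 0)


@pytest.fixture(scope="session")
def noiseless_tile_truth(noiseless_scene, subject):
    return simulate.render_tile(noiseless_scene, subject, 0)


def draw_mixture_intensities(rng, n, pi_low, low=2.2, high=3.4, sd=0.18):
    """Log-normal two-component intensities plus the true labels."""
    is_low = rng.random(n) < pi_low
    logx = np.where(is_low, rng.normal(low, sd, n), rng.normal(high, sd, n))
    return 10.0 ** logx, is_low
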