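import numpy as np
import pytest

from chronoplex import synthdata as sd


@pytest.fixture(scope="session")
def small_timelapse():
    """Standard small defocus-stack movie with ground truth (shared; read-only)."""
    params = sd.FocalSurfaceSimParams(shape=(4, 20, 128, 128), seed=7)
    movie, gt = sd.gen_focal_timelapse(params)
    return movie, gt


@pytest.fixture(scope="session")
def textured_frame():
    """A band-limited random texture used as a registration target."""
    rng = np.random.default_rng(11)
    return sd.band_limited_texture((128, 128), 4.0, rng)


@pytest.fixture(scope="session")
def noiseless_reporter():
    """Noiseless reporter photometry trace with its ground truth."""
    params = sd.PhotometrySimParams(noise_sd=0.0, seed=0)
    return sd.gen_photometry(params)
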