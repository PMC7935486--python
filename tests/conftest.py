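import numpy as np
import pytest

import cochleaflow as cf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_coupled_traj():
    """A reduced coupled chain that still develops sustained wave trains."""
    params = cf.ModelParams(mode="coupled", N=300)
    return cf.run(params, duration=1500.0, record_interval=1.0,
                  discard=700.0, seed=7)


@pytest.fixture(scope="session")
def wave_movie():
    """Default-condition synthetic movie (flow 0.24 apex-ward, wave 0.42
    base-ward, 168-µm wavelength, 24-min lag)."""
    spec = cf.WaveMovieSpec(noise_sd=0.01)
    fret, cfp, truth = cf.make_wave_movie(spec)
    return spec, fret, cfp, truth


@pytest.fixture(scope="session")
def textured_frame(rng):
    from scipy import ndimage
    return ndimage.gaussian_filter(rng.standard_normal((128, 200)), 3.0)
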