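import numpy as np
import pytest

from epimech.synth import (RecoilSimParams, simulate_recoil_track,
                           synth_epithelium_image)


@pytest.fixture
def noiseless_track():
    """Noise-free Kelvin-Voigt track: L0=2, D=1.5, tau=10, 4 s frames."""
    return simulate_recoil_track(
        RecoilSimParams(L0=2.0, D=1.5, tau=10.0, frame_interval=4.0,
                        n_pre=1, n_post=9, noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def epithelium_pair():
    """Uniform and punctate epithelium with identical geometry (same seed)."""
    uniform = synth_epithelium_image(n_cells=20, pixel_size=0.1,
                                     punctateness=0.0, background_noise_sd=0.0,
                                     field_um=20.0, seed=11)
    punctate = synth_epithelium_image(n_cells=20, pixel_size=0.1,
                                      punctateness=0.5, background_noise_sd=0.0,
                                      field_um=20.0, seed=11)
    return uniform, punctate


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
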