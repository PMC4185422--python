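import numpy as np
import pytest

from vesiflux import scenes


def clean_spec(**kwargs) -> scenes.SceneSpec:
    """Noise-free, PSF-free, background-free spec for exact-arithmetic tests."""
    defaults = dict(
        image_shape=(16, 128, 128),
        n_vesicles=5,
        psf_sigma_nm=(0.0, 0.0, 0.0),
        photon_scale=0.0,
        read_noise_sd=0.0,
        membrane_background={},
        macropinosome_rate=0.0,
        density_check="ignore",
        rng_seed=0,
    )
    defaults.update(kwargs)
    return scenes.SceneSpec(**defaults)


@pytest.fixture(scope="session")
def small_scene():
    """A realistic small scene (noise + PSF on) shared across tests."""
    spec = scenes.SceneSpec(
        image_shape=(20, 160, 160),
        n_vesicles=60,
        cargo_positive_fraction=0.8,
        macropinosome_rate=0.0,
        density_check="ignore",
        rng_seed=42,
    )
    stack, truth = scenes.generate_scene(spec)
    return spec, stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
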