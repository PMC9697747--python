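import numpy as np
import pytest

from dentalhsi.calibration import ReferenceTile, flat_field_correct
from dentalhsi.synthetic import SceneParams, render_scene, table1_fixture

#: Reduced scene used throughout the suite: same forward model as the
#: 512x512x204 default, scaled to keep the suite fast.
TEST_SHAPE = (128, 128)
TEST_BANDS = 60


@pytest.fixture(scope="session")
def visible_grid():
    """A 5 nm wavelength grid covering the colorimetric range."""
    return np.arange(400.0, 781.0, 5.0)


@pytest.fixture(scope="session")
def table1_profiles():
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_by_id(table1_profiles):
    return {p.tooth_id: p for p in table1_profiles}


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-noise scene at the reduced test size, with its calibrated
    reflectance cube and quality masks."""
    params = SceneParams(shape=TEST_SHAPE, n_bands=TEST_BANDS, seed=20220)
    raw, dark, gray, truth = render_scene(params)
    tile = ReferenceTile.flat(raw.wavelengths, params.tile_reflectance)
    reflectance, quality = flat_field_correct(
        raw, dark, gray, tile, full_scale=params.full_scale
    )
    return params, reflectance, quality, truth


@pytest.fixture(scope="session")
def clean_scene():
    """Zero-noise scene (float counts) for exact-inversion checks."""
    params = SceneParams(shape=(96, 96), n_bands=40, noise_sd=0.0, seed=7)
    raw, dark, gray, truth = render_scene(params)
    return params, raw, dark, gray, truth
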