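import numpy as np
import pytest

from fluocube import SimConfig, flat_field, generate_scene, make_band_grid
from fluocube.cube_io import Cube


@pytest.fixture
def default_cfg():
    return SimConfig()


@pytest.fixture
def small_cfg():
    """A fast 48x48 scene configuration with the default five groups."""
    return SimConfig(image_height=48, image_width=48)


@pytest.fixture
def noiseless_cfg():
    """No scatter, no offset, no noise, no illumination falloff, no dark current.

    With dark current present the Eq-style subtraction (x + d) − d is exact
    only in exact arithmetic; zeroing it makes the calibration identity exact
    in float64 too.
    """
    return SimConfig(
        image_height=32,
        image_width=32,
        scatter_sd=0.0,
        offset_sd=0.0,
        noise_sd=0.0,
        illum_gradient=0.0,
        dark_level=0.0,
    )


@pytest.fixture
def calibrated_scene(small_cfg):
    """One calibrated control-group scene with its ground truth."""
    scene = generate_scene("Cg", small_cfg, seed=42)
    cal = flat_field(scene.raw, scene.white, scene.dark)
    return scene, cal


def make_cube(data, wavelengths=None, **meta):
    data = np.asarray(data, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(data.shape[2], dtype=float)
    return Cube(data, wavelengths, meta)


@pytest.fixture
def uniform_grid_cube():
    """A tiny cube on the canonical 25-band 603-870 nm grid."""
    wl = make_band_grid(SimConfig())
    data = np.ones((4, 4, 25))
    return Cube(data, wl, {"kind": "calibrated"})
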