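"""Shared fixtures: a small optical system, LED geometry and scenes."""

import numpy as np
import pytest

from fpmfa import (LedGridSpec, OpticalSystem, SceneSpec, build_led_geometry,
                   hr_grid, make_pupil, synth_diatom_scene)


@pytest.fixture(scope="session")
def optics():
    """64-pixel detector crop: λ=0.52 µm, NA 0.25, 4×, 2 µm detector pitch."""
    return OpticalSystem(wavelength_um=0.52, na_mo=0.25, magnification=4.0,
                         pixel_pitch_um=2.0, grid_size=64)


@pytest.fixture(scope="session")
def led_spec():
    """5×5 LED matrix reaching NA_ill ≈ 0.24 (synthetic aperture ≈ 2 NA)."""
    return LedGridSpec(rows=5, cols=5, pitch_mm=6.0, height_mm=70.0)


@pytest.fixture(scope="session")
def geometry(led_spec, optics):
    return build_led_geometry(led_spec, optics)


@pytest.fixture(scope="session")
def pupil(optics):
    return make_pupil(optics)


@pytest.fixture(scope="session")
def diatom_field(optics, geometry):
    """A deterministic moderately dense healthy scene on the HR grid."""
    shape, pixel = hr_grid(optics, geometry)
    return synth_diatom_scene(SceneSpec(density_per_mm2=4000, seed=3),
                              shape, pixel)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
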