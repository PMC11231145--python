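"""Scene generator and forward-model tests, including a brute-force oracle."""

import numpy as np
import pytest

from fpmfa import (HighResField, LedGeometry, NoiseSpec, OpticalSystem,
                   SceneSpec, add_noise, forward_acquire, hr_grid, make_pupil,
                   severity_from_dose, synth_diatom_scene, two_point_target,
                   upsampling_factor)
from fpmfa.simulate import shift_samples


def brute_force_acquire(field, pupil_values, shift, n_lr):
    """Direct evaluation of I = |IFT{O(ν−ν_n)P(ν)}|² by explicit DFT sums.

    Independent of the package's FFT helpers: the object spectrum, the
    windowed product and the inverse transform are all written as plain
    nested sums in the centered-index convention (forward transform divides
    by the pixel count, inverse does not).
    """
    o = field.data
    n_hr = o.shape[0]
    c_hr, c_lr = n_hr // 2, n_lr // 2
    ks = np.arange(n_hr) - c_hr
    O = np.zeros((n_hr, n_hr), dtype=complex)
    rr = np.arange(n_hr)
    for iy, ky in enumerate(ks):
        for ix, kx in enumerate(ks):
            ph = np.exp(-2j * np.pi * (ky * rr[:, None] + kx * rr[None, :])
                        / n_hr)
            O[iy, ix] = (o * ph).sum() / n_hr**2
    qs = np.arange(n_lr) - c_lr
    phi = np.zeros((n_lr, n_lr), dtype=complex)
    for iy, qy in enumerate(qs):
        for ix, qx in enumerate(qs):
            phi[iy, ix] = O[qy - shift[0] + c_hr, qx - shift[1] + c_hr] \
                * pupil_values[iy, ix]
    I = np.zeros((n_lr, n_lr))
    mm = np.arange(n_lr)
    for my in mm:
        for mx in mm:
            ph = np.exp(2j * np.pi * (qs[:, None] * my + qs[None, :] * mx)
                        / n_lr)
            I[my, mx] = abs((phi * ph).sum()) ** 2
    return I


class TestScene:
    def test_empty_scene_is_unit_field(self, optics, geometry):
        shape, pixel = hr_grid(optics, geometry)
        f = synth_diatom_scene(SceneSpec(density_per_mm2=0.0, seed=0),
                               shape, pixel)
        assert np.allclose(f.data, 1.0)

    def test_same_seed_bit_identical(self, optics, geometry):
        shape, pixel = hr_grid(optics, geometry)
        spec = SceneSpec(density_per_mm2=4000, stress=0.5, seed=7)
        a = synth_diatom_scene(spec, shape, pixel)
        b = synth_diatom_scene(spec, shape, pixel)
        assert np.array_equal(a.data, b.data)

    def test_pure_phase_object(self, diatom_field):
        assert np.allclose(np.abs(diatom_field.data), 1.0, atol=1e-12)

    def test_stress_grows_segmented_area(self, optics, geometry):
        shape, pixel = hr_grid(optics, geometry)
        masks = {}
        for s in (0.0, 1.0):
            f = synth_diatom_scene(
                SceneSpec(density_per_mm2=4000, stress=s, seed=5),
                shape, pixel)
            masks[s] = (f.meta["cell_mask"] | f.meta["leak_mask"]).sum()
        assert masks[1.0] > masks[0.0]

    def test_stress_lowers_mean_peak_phase(self, optics, geometry):
        shape, pixel = hr_grid(optics, geometry)
        peaks = {}
        for s in (0.0, 1.0):
            f = synth_diatom_scene(
                SceneSpec(density_per_mm2=4000, stress=s, seed=5),
                shape, pixel)
            peaks[s] = f.meta["cell_peaks_rad"].mean()
        assert peaks[1.0] < peaks[0.0]

    def test_overcrowded_scene_raises(self, optics, geometry):
        shape, pixel = hr_grid(optics, geometry)
        with pytest.raises(RuntimeError, match="density"):
            synth_diatom_scene(SceneSpec(density_per_mm2=2e5, seed=0),
                               shape, pixel)

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_stress_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            SceneSpec(stress=bad)


class TestSeverityMap:
    def test_control_is_zero_and_saturates(self):
        assert severity_from_dose(0.0, "T3") == 0.0
        assert severity_from_dose(1e4, "T3") == 1.0

    def test_longer_exposure_is_more_severe(self):
        for dose in (5.0, 15.0, 35.0):
            assert severity_from_dose(dose, "T3") > severity_from_dose(dose, "T2")


class TestForward:
    def test_uniform_object_gives_unit_intensity(self, optics, geometry,
                                                 pupil):
        shape, pixel = hr_grid(optics, geometry)
        f = HighResField(np.ones(shape, complex), pixel)
        stack = forward_acquire(f, pupil, geometry, optics)
        assert np.allclose(stack.images[0], 1.0, atol=1e-10)

    def test_dark_field_dimmer_than_bright_field(self, optics):
        # geometry with genuinely dark-field outer LEDs (NA_ill up to 0.44)
        from fpmfa import LedGridSpec, build_led_geometry
        geom = build_led_geometry(LedGridSpec(5, 5, 12.0, 70.0), optics)
        shape, pixel = hr_grid(optics, geom)
        f = synth_diatom_scene(SceneSpec(density_per_mm2=4000, seed=3),
                               shape, pixel)
        stack = forward_acquire(f, make_pupil(optics), geom, optics)
        na_ill = geom.illumination_na(optics.wavelength_um)
        assert na_ill[-1] > optics.na_mo  # truly dark-field
        assert stack.images[-1].mean() < stack.images[0].mean()

    def test_low_pass_energy_contract(self, optics, geometry, pupil,
                                      diatom_field):
        stack = forward_acquire(diatom_field, pupil, geometry, optics)
        for img in stack.images:
            assert img.mean() <= np.mean(np.abs(diatom_field.data) ** 2) + 1e-9

    def test_matches_brute_force_oracle(self, rng):
        n_lr, up = 8, 2
        opt = OpticalSystem(wavelength_um=0.5, na_mo=0.4, magnification=1.0,
                            pixel_pitch_um=0.5, grid_size=n_lr)
        shape = (n_lr * up, n_lr * up)
        field = HighResField(
            np.exp(1j * rng.uniform(-1, 1, shape))
            * (0.5 + rng.uniform(0, 1, shape)), opt.sample_pitch_um / up)
        geom = LedGeometry(np.array([[0.0, 0.0], [0.25, -0.25]]))
        pupil = make_pupil(opt)
        stack = forward_acquire(field, pupil, geom, opt)
        shifts = shift_samples(geom, opt)
        for i in range(geom.n_leds):
            expected = brute_force_acquire(field, pupil.values, shifts[i],
                                           n_lr)
            assert np.allclose(stack.images[i], expected, atol=1e-12)

    def test_shift_outside_support_names_led(self, optics, geometry, pupil,
                                             diatom_field):
        geom = LedGeometry(np.array([[0.0, 0.0], [0.0, 30.0]]))
        with pytest.raises(ValueError, match="LED 1"):
            forward_acquire(diatom_field, pupil, geom, optics)

    def test_upsampling_factor_is_even_and_covers_aperture(self, optics,
                                                           geometry):
        u = upsampling_factor(optics, geometry)
        assert u % 2 == 0
        na_syn = optics.na_mo + optics.wavelength_um \
            * geometry.max_frequency()
        assert u >= na_syn / optics.na_mo


class TestNoise:
    def test_noiseless_limit_identity(self, optics, geometry, pupil,
                                      diatom_field):
        stack = forward_acquire(diatom_field, pupil, geometry, optics)
        out = add_noise(stack, NoiseSpec(photons_per_unit=None,
                                         read_sigma=0.0), seed=0)
        assert np.array_equal(out.images, stack.images)

    def test_shot_noise_variance_scales_with_budget(self):
        # 10^4 iid pixels at intensity 0.5: var ≈ mean / budget
        budget = 2000.0
        geom = LedGeometry(np.zeros((1, 2)))
        opt = OpticalSystem(0.5, 0.4, 1.0, 0.5, 100)
        from fpmfa import IntensityStack
        stack = IntensityStack(np.full((1, 100, 100), 0.5), geom, opt)
        noisy = add_noise(stack, NoiseSpec(photons_per_unit=budget), seed=9)
        var = noisy.images.var()
        assert np.isclose(var, 0.5 / budget, rtol=0.1)

    def test_seeded_determinism(self, optics, geometry, pupil, diatom_field):
        stack = forward_acquire(diatom_field, pupil, geometry, optics)
        spec = NoiseSpec(photons_per_unit=1e4, read_sigma=0.01)
        a = add_noise(stack, spec, seed=5)
        b = add_noise(stack, spec, seed=5)
        assert np.array_equal(a.images, b.images)

    def test_negative_budget_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(photons_per_unit=-1.0)


class TestTwoPointTarget:
    def test_separation_recorded_and_peaks_present(self, optics, geometry):
        shape, pixel = hr_grid(optics, geometry)
        t = two_point_target(shape, pixel, separation_um=1.0,
                             point_fwhm_um=0.4)
        c = shape[0] // 2
        profile = np.abs(t.data[c]) ** 2
        half = 0.5 / pixel
        assert profile[int(c - half)] > 10 * profile[4]
        assert t.meta["separation_um"] == 1.0
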