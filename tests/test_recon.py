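"""Retrieval tests: update-equation oracle, fixed points, recovery quality."""

import numpy as np
import pytest

from fpmfa import (HighResField, LedGeometry, OpticalSystem, ReconConfig,
                   SceneSpec, build_led_geometry, defocus_phase,
                   extract_phase_map, forward_acquire, hr_grid,
                   initialize_state, make_pupil, reconstruct,
                   synth_diatom_scene, two_point_target, update_once)
from fpmfa.simulate import shift_samples


def phase_rmse(rec, truth):
    """RMSE of the phase difference after removing the global phase offset."""
    d = np.angle(rec.data * np.conj(truth.data))
    off = np.angle(np.mean(np.exp(1j * d)))
    return float(np.sqrt(np.mean(np.angle(np.exp(1j * (d - off))) ** 2)))


def oracle_update(O_hr, P, support, image, shift, d1, d2):
    """Independent transcription of the object/pupil update equations.

    Written directly from the update rules with plain numpy FFT calls: form
    the windowed product, inverse transform, replace the amplitude with √I,
    transform back, and apply the two gradient-style corrections with the
    step maps |P|P*/(max|P|(|P|²+δ1)) and |O_w|O_w*/(max|O|(|O_w|²+δ2)).
    """
    O = O_hr.copy()
    n_hr, n_lr = O.shape[0], P.shape[0]
    sy, sx = shift
    y0 = n_hr // 2 - n_lr // 2 - sy
    x0 = n_hr // 2 - n_lr // 2 - sx
    w = O[y0:y0 + n_lr, x0:x0 + n_lr].copy()
    phi = w * P
    Phi = np.fft.ifft2(np.fft.ifftshift(phi), norm="forward")
    absPhi = np.abs(Phi)
    ratio = np.where(absPhi > 0, Phi / np.where(absPhi > 0, absPhi, 1.0), 1.0)
    Phi_p = np.sqrt(image) * ratio
    phi_p = np.fft.fftshift(np.fft.fft2(Phi_p, norm="forward"))
    diff = phi_p - phi
    G = np.abs(P) * np.conj(P) / (np.abs(P).max()
                                  * (np.abs(P) ** 2 + d1))
    H = np.abs(w) * np.conj(w) / (np.abs(O).max()
                                  * (np.abs(w) ** 2 + d2))
    O[y0:y0 + n_lr, x0:x0 + n_lr] = w + G * diff
    P_new = P + H * diff
    P_new[~support] = 0.0
    return O, P_new


@pytest.fixture(scope="module")
def noiseless_stack(optics, geometry, pupil, diatom_field):
    from fpmfa import forward_acquire
    return forward_acquire(diatom_field, pupil, geometry, optics)


class TestInitialization:
    def test_uniform_stack_initializes_to_dc_delta(self, optics, geometry):
        shape, pixel = hr_grid(optics, geometry)
        f = HighResField(np.ones(shape, complex), pixel)
        stack = forward_acquire(f, make_pupil(optics), geometry, optics)
        state = initialize_state(stack, geometry, optics, ReconConfig())
        c = state.spectrum.shape[0] // 2
        dc = abs(state.spectrum[c, c])
        rest = np.abs(state.spectrum).sum() - dc
        assert rest <= 1e-10 * dc

    def test_pupil_initialized_flat_on_support(self, optics, geometry,
                                               noiseless_stack):
        state = initialize_state(noiseless_stack, geometry, optics,
                                 ReconConfig())
        p = state.pupil
        assert np.isclose(p.amplitude.sum(), p.support.sum())
        assert np.allclose(p.phase[p.support], 0.0)

    def test_initial_guess_reproduces_central_image(self, optics, geometry):
        # smooth real-amplitude object within the pupil band: the up-sampled
        # √I guess pushed through the forward model returns the same image
        shape, pixel = hr_grid(optics, geometry)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        amp = 1.0 + 0.1 * np.cos(2 * np.pi * yy / shape[0]) \
            * np.cos(2 * np.pi * xx / shape[1])
        f = HighResField(amp.astype(complex), pixel)
        stack = forward_acquire(f, make_pupil(optics), geometry, optics)
        state = initialize_state(stack, geometry, optics, ReconConfig())
        guess = HighResField(
            np.fft.ifft2(np.fft.ifftshift(state.spectrum), norm="forward"),
            pixel)
        stack2 = forward_acquire(guess, make_pupil(optics), geometry, optics)
        err = np.abs(stack2.images[0] - stack.images[0]).max()
        assert err < 1e-6 * stack.images[0].max()

    def test_no_bright_field_led_rejected(self, optics, noiseless_stack):
        geom = LedGeometry(np.array([[0.0, 0.9], [0.9, 0.0]]))
        from fpmfa import IntensityStack
        bad = IntensityStack(noiseless_stack.images[:2], geom, optics)
        with pytest.raises(ValueError, match="bright-field"):
            initialize_state(bad, geom, optics, ReconConfig())


class TestUpdateOnce:
    def test_matches_independent_oracle(self, rng):
        n_lr, up = 8, 2
        opt = OpticalSystem(0.5, 0.4, 1.0, 0.5, n_lr)
        n_hr = n_lr * up
        cfg = ReconConfig(delta1=1e-3, delta2=2e-3, recover_pupil=True)
        image = rng.uniform(0.1, 1.0, (n_lr, n_lr))
        spectrum = (rng.standard_normal((n_hr, n_hr))
                    + 1j * rng.standard_normal((n_hr, n_hr)))
        pupil = make_pupil(opt)
        pupil.values = pupil.values * np.exp(
            1j * rng.uniform(-0.3, 0.3, pupil.values.shape))
        pupil.project()
        shift = (1, -2)

        from fpmfa.recon import ReconState
        state = ReconState(spectrum=spectrum.copy(), pupil=pupil.copy(),
                           optics=opt, upsampling=up)
        update_once(state, image, shift, cfg)
        O_exp, P_exp = oracle_update(spectrum, pupil.values, pupil.support,
                                     image, shift, cfg.delta1, cfg.delta2)
        assert np.allclose(state.spectrum, O_exp, atol=1e-12)
        assert np.allclose(state.pupil.values, P_exp, atol=1e-12)

    def test_exact_data_is_fixed_point(self, optics, geometry, pupil,
                                       diatom_field, noiseless_stack):
        cfg = ReconConfig(recover_pupil=True)
        state = initialize_state(noiseless_stack, geometry, optics, cfg)
        state.spectrum[:] = diatom_field.spectrum()
        before = state.spectrum.copy()
        shifts = shift_samples(geometry, optics)
        for i in range(geometry.n_leds):
            update_once(state, noiseless_stack.images[i], shifts[i], cfg, i)
        rel = np.abs(state.spectrum - before).max() / np.abs(before).max()
        assert rel <= 1e-9

    def test_negative_intensity_rejected(self, optics, geometry,
                                         noiseless_stack):
        cfg = ReconConfig()
        state = initialize_state(noiseless_stack, geometry, optics, cfg)
        with pytest.raises(ValueError):
            update_once(state, -np.ones((optics.grid_size,) * 2), (0, 0),
                        cfg)


class TestReconstruct:
    def test_noiseless_phase_recovery_below_tolerance(self, optics, geometry,
                                                      pupil, diatom_field,
                                                      noiseless_stack):
        rec, _, misfits = reconstruct(noiseless_stack, geometry, optics,
                                      ReconConfig(n_outer=20,
                                                  recover_pupil=False))
        assert phase_rmse(rec, diatom_field) < 0.05
        assert misfits[-1] < misfits[0] / 10

    def test_misfit_non_increasing_on_noiseless_data(self, optics, geometry,
                                                     noiseless_stack):
        _, _, misfits = reconstruct(noiseless_stack, geometry, optics,
                                    ReconConfig(n_outer=12,
                                                recover_pupil=False,
                                                misfit_tol=0.0))
        m = np.asarray(misfits)
        assert np.all(m[1:] <= m[:-1] * 1.01)

    def test_pupil_support_conserved(self, optics, geometry,
                                     noiseless_stack):
        _, pup, _ = reconstruct(noiseless_stack, geometry, optics,
                                ReconConfig(n_outer=3, recover_pupil=True))
        assert np.all(pup.values[~pup.support] == 0)

    def test_pupil_recovery_reduces_rmse_under_defocus(self, optics,
                                                       geometry,
                                                       diatom_field):
        aberrated = make_pupil(optics, phase=defocus_phase(optics, 8.0))
        stack = forward_acquire(diatom_field, aberrated, geometry, optics)
        rmse = {}
        for flag in (False, True):
            rec, _, _ = reconstruct(stack, geometry, optics,
                                    ReconConfig(n_outer=20,
                                                recover_pupil=flag))
            rmse[flag] = phase_rmse(rec, diatom_field)
        assert rmse[True] < rmse[False]

    def test_single_central_led_returns_upsampled_sqrt_image(self, optics):
        geom = LedGeometry(np.zeros((1, 2)))
        shape = (optics.grid_size * 2,) * 2
        pixel = optics.sample_pitch_um / 2
        yy = np.mgrid[0:shape[0]][:, None]
        amp = 1.0 + 0.05 * np.cos(2 * np.pi * yy / shape[0])
        f = HighResField(np.broadcast_to(amp, shape).astype(complex), pixel)
        stack = forward_acquire(f, make_pupil(optics), geom, optics)
        rec, _, _ = reconstruct(stack, geom, optics,
                                ReconConfig(n_outer=1, recover_pupil=False))
        # phase constant, amplitude matches √I up-sampled on the LR samples
        assert np.ptp(np.angle(rec.data)) < 1e-6
        lr_samples = np.abs(rec.data[::2, ::2])
        assert np.allclose(lr_samples**2, stack.images[0], atol=1e-6)

    def test_resolution_doubling_on_two_point_target(self, optics):
        from fpmfa import LedGridSpec
        geom = build_led_geometry(LedGridSpec(5, 5, 12.0, 70.0), optics)
        shape, pixel = hr_grid(optics, geom)
        sep = 0.8  # µm: below λ/2NA_MO = 1.04, above λ/2NA_syn = 0.38
        target = two_point_target(shape, pixel, separation_um=sep,
                                  point_fwhm_um=0.35)
        stack = forward_acquire(target, make_pupil(optics), geom, optics)
        rec, _, _ = reconstruct(stack, geom, optics,
                                ReconConfig(n_outer=20, recover_pupil=False))

        def dip(profile):
            c = len(profile) // 2
            left = np.argmax(profile[:c])
            right = c + np.argmax(profile[c:])
            peak = min(profile[left], profile[right])
            return (peak - profile[left:right + 1].min()) / peak

        c = shape[0] // 2
        win = int(2.0 * sep / pixel)
        hr_profile = np.abs(rec.data[c]) ** 2
        assert dip(hr_profile[c - win:c + win + 1]) >= 0.2
        n_lr = optics.grid_size
        lr_profile = stack.images[0][n_lr // 2]
        lwin = max(2, int(2.0 * sep / optics.sample_pitch_um))
        assert dip(lr_profile[n_lr // 2 - lwin:n_lr // 2 + lwin + 1]) < 0.05

    def test_divergence_guard_aborts_with_history(self, optics, geometry,
                                                  noiseless_stack,
                                                  monkeypatch):
        # stub the per-LED update to report escalating misfits: the outer
        # loop must abort once the total exceeds 10× the first loop's value
        import fpmfa.recon as recon_mod
        calls = {"n": 0}

        def escalating(state, image, shift, config, led_index=None):
            calls["n"] += 1
            return float(calls["n"] ** 3)

        monkeypatch.setattr(recon_mod, "update_once", escalating)
        with pytest.raises(RuntimeError, match="diverged"):
            recon_mod.reconstruct(noiseless_stack, geometry, optics,
                                  ReconConfig(n_outer=30,
                                              recover_pupil=False))


class TestPhaseMap:
    def test_unit_field_gives_zero_phase(self):
        f = HighResField(np.ones((16, 16), complex), 0.5)
        assert np.allclose(extract_phase_map(f).values, 0.0)

    def test_constant_offset_and_flattening(self):
        f = HighResField(np.full((32, 32), np.exp(1j * 0.3)), 0.5)
        pm = extract_phase_map(f)
        assert np.allclose(pm.values, 0.3)
        flat = extract_phase_map(f, flatten=True)
        assert np.allclose(flat.values, 0.0, atol=1e-9)

    def test_flattening_recovers_blob_on_tilted_background(self):
        ny = nx = 96
        yy, xx = np.mgrid[0:ny, 0:nx]
        tilt = 0.002 * xx + 0.001 * yy
        blob = 0.8 * np.exp(-((yy - 48) ** 2 + (xx - 48) ** 2) / (2 * 5**2))
        f = HighResField(np.exp(1j * (tilt + blob)), 0.5)
        pm = extract_phase_map(f, flatten=True)
        assert abs(pm.values.max() - 0.8) / 0.8 < 0.05

    def test_wraparound_warns(self):
        rngl = np.random.default_rng(0)
        vals = np.exp(1j * np.pi * np.sign(rngl.standard_normal((32, 32))))
        f = HighResField(vals, 0.5)
        with pytest.warns(UserWarning, match="wrap"):
            extract_phase_map(f)
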