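"""Retrieve the high-resolution phase map from a simulated stack.

Runs the iterative object+pupil retrieval on a noiseless acquisition and
compares the recovered phase with the generator's ground truth, then repeats
with a defocused objective to show what pupil recovery buys.
"""

import numpy as np

from fpmfa import (LedGridSpec, OpticalSystem, ReconConfig, SceneSpec,
                   build_led_geometry, defocus_phase, forward_acquire,
                   hr_grid, make_pupil, reconstruct, synth_diatom_scene)


def phase_rmse(rec, truth):
    d = np.angle(rec.data * np.conj(truth.data))
    off = np.angle(np.mean(np.exp(1j * d)))
    return float(np.sqrt(np.mean(np.angle(np.exp(1j * (d - off))) ** 2)))


optics = OpticalSystem(0.52, 0.25, 4.0, 2.0, 64)
geometry = build_led_geometry(LedGridSpec(5, 5, 6.0, 70.0), optics)
shape, hr_pixel = hr_grid(optics, geometry)
truth = synth_diatom_scene(SceneSpec(density_per_mm2=4000, seed=3),
                           shape, hr_pixel)

stack = forward_acquire(truth, make_pupil(optics), geometry, optics)
rec, pupil, misfits = reconstruct(stack, geometry, optics,
                                  ReconConfig(n_outer=20,
                                              recover_pupil=False))
print(f"noiseless stack, {geometry.n_leds} LEDs, J=20 outer loops:")
print(f"  relative misfit {misfits[0]:.2e} -> {misfits[-1]:.2e}")
print(f"  phase RMSE vs ground truth: {phase_rmse(rec, truth):.4f} rad")
print("  (the peak diatom phase is ~1.2 rad, so the map is quantitative)")

aberrated = make_pupil(optics, phase=defocus_phase(optics, 8.0))
ab_stack = forward_acquire(truth, aberrated, geometry, optics)
for flag in (False, True):
    r, p, _ = reconstruct(ab_stack, geometry, optics,
                          ReconConfig(n_outer=20, recover_pupil=flag))
    print(f"8 µm defocus, pupil recovery {'on ' if flag else 'off'}: "
          f"phase RMSE {phase_rmse(r, truth):.4f} rad")
print("recovering the pupil absorbs the unknown aberration instead of "
      "folding it into the object estimate.")
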