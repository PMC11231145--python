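"""Calibrate the dose curves and classify held-out fields into intervals.

Generates a 72 h-exposure (T3) calibration series over the assay's dose
ladder {0, 5, 10, 15, 25, 35, 50} µM, fits the exponential MSL curve and
the low-dose cubic entropy curve, then runs the two-step interval classifier
on held-out fields.  Descriptors are measured on ground-truth phase maps
here so the example runs in seconds; the test suite runs the same protocol
through the full FPM reconstruction.
"""

from fpmfa import (LedGridSpec, OpticalSystem, SceneSpec,
                   build_decision_table, classify_dose)
from fpmfa.study import AssaySettings, calibrate_series, dose_series

optics = OpticalSystem(0.52, 0.25, 4.0, 2.0, 256)
leds = LedGridSpec(5, 5, 6.0, 70.0)
scene = SceneSpec(density_per_mm2=6000)
settings = AssaySettings()

cal = dose_series(optics, leds, scene, n_fields=3, seed=5,
                  settings=settings, reconstruct_fields=False)
msl_model, entropy_model = calibrate_series(cal, settings)
a, b, c = msl_model.coefficients
print(f"MSL calibration:  y = {a:.3f}·exp({b:.4f}·x) + {c:.3f}   "
      f"(RMS residual {msl_model.residual_scale:.4f})")
print(f"entropy cubic fit over [0, {settings.low_dose_max_um:g}] µM, "
      f"RMS residual {entropy_model.residual_scale:.5f} bits")

table = build_decision_table()
held_out = dose_series(optics, leds, scene, n_fields=2, seed=321,
                       settings=settings, reconstruct_fields=False)
hits = 0
for r in held_out:
    call = classify_dose(r.msl, r.delta_s_bits, msl_model, entropy_model,
                         table)
    truth = table.label_for_dose(r.dose_um)
    hits += call.label == truth
    steps = "+".join(call.steps_run)
    print(f"  true {r.dose_um:4.0f} µM  MSL {r.msl:.3f}  "
          f"-> {call.label:16s} ({steps})"
          f"  {'hit' if call.label == truth else 'MISS'}")
print(f"{hits}/{len(held_out)} held-out fields classified into the "
      "interval containing their true dose; the entropy step refines only "
      "the lowest MSL interval, giving seven possible labels in total.")
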