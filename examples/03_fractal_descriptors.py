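"""Multi-scale lacunarity and texture entropy of a phase-contrast map.

Measures GL, LL, MSL = GL/LL and the range GLCM entropy Δs on a control
field and on a heavily copper-stressed field, showing how membrane lysis and
cytoplasm leakage move the descriptors.
"""

from fpmfa import (LedGridSpec, OpticalSystem, SceneSpec, build_led_geometry,
                   extract_phase_map, hr_grid, synth_diatom_scene)
from fpmfa.study import AssaySettings, measure_descriptors

optics = OpticalSystem(0.52, 0.25, 4.0, 2.0, 256)
geometry = build_led_geometry(LedGridSpec(5, 5, 6.0, 70.0), optics)
shape, hr_pixel = hr_grid(optics, geometry)
settings = AssaySettings()   # fixed threshold, ladder 0.5–8 µm, 4 µm box

for label, stress in (("control (0 µM)", 0.0), ("severe stress", 0.9)):
    field = synth_diatom_scene(
        SceneSpec(density_per_mm2=6000, stress=stress, seed=7),
        shape, hr_pixel)
    pmap = extract_phase_map(field)
    d = measure_descriptors(pmap, settings)
    print(f"{label:15s}: GL={d.gl:6.3f}  LL={d.ll:6.3f}  "
          f"MSL={d.msl:6.3f}  Δs={d.delta_s_bits:.4f} bits")

print()
print("leaked cytoplasm fills the gaps between diatoms at the 4 µm box "
      "scale, so LL drops faster than GL and the ratio MSL rises; the "
      "extra fine structure also widens the directional spread of the "
      "co-occurrence entropy Δs.")
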