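"""Synthetic dose-calibration studies: generate, measure, fit, classify.

This module reproduces the assay protocol end to end on synthetic data: a
dose series of diatom fields is generated at severities mapped from the Cu
concentrations, each field is (optionally) pushed through the FPM forward
model and reconstruction, descriptors are measured, calibration curves are
fitted, and held-out fields are classified against their true dose interval.

Analysis settings are held fixed across a series (one threshold, one local
scale, one quantization range per experiment) so that descriptor differences
reflect the dose, not per-image re-tuning:

* binarization at a fixed phase threshold that captures both frustules and
  the fainter cytoplasm leaks,
* a gliding-box ladder spanning sub-cell to cell scales (0.5–8 µm),
* the local scale fixed at the frustule minor axis (the species is known in
  a calibration assay),
* GLCM quantization over a fixed low-phase window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .assay import CalibrationModel, fit_cubic, fit_exponential
from .lacunarity import (AssayDescriptors, binarize_phase, compute_descriptors,
                         global_lacunarity, gliding_box_lacunarity,
                         local_lacunarity, multi_scale_lacunarity)
from .optics import LedGridSpec, OpticalSystem, build_led_geometry, make_pupil
from .recon import PhaseMap, ReconConfig, extract_phase_map, reconstruct
from .simulate import (NoiseSpec, SceneSpec, add_noise, forward_acquire,
                       hr_grid, severity_from_dose, synth_diatom_scene)
from .texture import GlcmSpec, range_glcm_entropy

__all__ = ["AssaySettings", "measure_descriptors", "dose_series",
           "calibrate_series", "DEFAULT_DOSES_UM"]

DEFAULT_DOSES_UM = (0.0, 5.0, 10.0, 15.0, 25.0, 35.0, 50.0)


@dataclass(frozen=True)
class AssaySettings:
    """Fixed per-experiment analysis settings of a calibration series."""

    threshold_rad: float = 0.25
    ladder_um: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)
    r_local_um: float = 4.0
    glcm: GlcmSpec = field(default_factory=lambda: GlcmSpec(
        levels=64, distance=1, phase_range=(0.1, 0.6)))
    low_dose_max_um: float = 15.0

    def scales_px(self, pixel_um: float) -> list[int]:
        return sorted({max(1, round(s / pixel_um)) for s in self.ladder_um})

    def r_local_px(self, pixel_um: float) -> int:
        return max(2, round(self.r_local_um / pixel_um))


def measure_descriptors(pmap: PhaseMap, settings: AssaySettings,
                        fov_id: str = "", exposure: str = "T3",
                        dose_um: float | None = None) -> AssayDescriptors:
    """Descriptor row of one phase map under fixed series settings."""
    mask = binarize_phase(pmap, method="fixed", param=settings.threshold_rad)
    profile = gliding_box_lacunarity(mask,
                                     settings.scales_px(pmap.pixel_um))
    gl = global_lacunarity(profile)
    r_px = settings.r_local_px(pmap.pixel_um)
    ll = local_lacunarity(mask, r_px)
    desc = AssayDescriptors(gl=gl, ll=ll, msl=multi_scale_lacunarity(gl, ll),
                            r_local_um=r_px * pmap.pixel_um, fov_id=fov_id,
                            exposure=exposure, dose_um=dose_um)
    desc.delta_s_bits = range_glcm_entropy(pmap, settings.glcm)
    return desc


def dose_series(optics: OpticalSystem, leds: LedGridSpec, scene: SceneSpec,
                doses_um=DEFAULT_DOSES_UM, n_fields: int = 3,
                exposure: str = "T3", seed: int = 0,
                settings: AssaySettings = AssaySettings(),
                reconstruct_fields: bool = True,
                recon: ReconConfig = ReconConfig(n_outer=8,
                                                 recover_pupil=False),
                noise: NoiseSpec | None = None) -> list[AssayDescriptors]:
    """Descriptor rows for ``n_fields`` fields of view per dose.

    Each field gets its own child seed derived from ``seed``; the severity of
    each dose follows :func:`severity_from_dose` for the given exposure.
    With ``reconstruct_fields`` the descriptors are measured on reconstructed
    phase maps (the assay's realistic path), otherwise on the ground truth.
    """
    geom = build_led_geometry(leds, optics)
    shape, hr_pixel = hr_grid(optics, geom)
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(len(doses_um) * n_fields))
    rows: list[AssayDescriptors] = []
    for dose in doses_um:
        sev = severity_from_dose(dose, exposure)
        for k in range(n_fields):
            fseed = int(next(child).generate_state(1)[0] % (2**31))
            spec = dataclasses.replace(scene, stress=sev, exposure=exposure,
                                       seed=fseed)
            truth = synth_diatom_scene(spec, shape, hr_pixel)
            if reconstruct_fields:
                stack = forward_acquire(truth, make_pupil(optics), geom,
                                        optics)
                if noise is not None:
                    stack = add_noise(stack, noise, fseed)
                recfield, _, _ = reconstruct(stack, geom, optics, recon)
                pmap = extract_phase_map(recfield, flatten=True)
            else:
                pmap = extract_phase_map(truth)
            rows.append(measure_descriptors(
                pmap, settings, fov_id=f"d{dose:g}_f{k}", exposure=exposure,
                dose_um=dose))
    return rows


def calibrate_series(rows: list[AssayDescriptors],
                     settings: AssaySettings = AssaySettings(),
                     exposure: str = "T3",
                     ) -> tuple[CalibrationModel, CalibrationModel | None]:
    """Fit the MSL exponential and low-dose entropy cubic from a series.

    The exponential uses every field; the cubic uses the fields at doses up
    to ``settings.low_dose_max_um``.  Duplicate dose values (several fields
    per dose) are jittered infinitesimally to satisfy distinctness, which
    leaves the least-squares fits unchanged.
    """
    doses = np.array([r.dose_um for r in rows], dtype=float)
    msl = np.array([r.msl for r in rows], dtype=float)
    jitter = np.arange(len(doses)) * 1e-9
    import warnings
    with warnings.catch_warnings():
        # replicate fields at the same dose scatter around their mean, which
        # the per-point monotonicity check would flag spuriously
        warnings.filterwarnings("ignore", message=".*not monotone.*")
        msl_model = fit_exponential(doses + jitter, msl, exposure=exposure)

    low = [r for r in rows if r.dose_um <= settings.low_dose_max_um
           and r.delta_s_bits is not None]
    entropy_model = None
    if len(low) >= 5:
        ld = np.array([r.dose_um for r in low], dtype=float)
        ds = np.array([r.delta_s_bits for r in low], dtype=float)
        entropy_model = fit_cubic(ld + np.arange(len(ld)) * 1e-9, ds,
                                  exposure=exposure)
    return msl_model, entropy_model
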