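"""End-to-end run configuration and the simulate→reconstruct→analyze chain.

A :class:`RunConfig` gathers every stage's parameters, round-trips through
YAML, and spawns a recorded child seed for each stochastic stage from the
global seed.  :func:`run_pipeline` executes the configured stages, writes
each intermediate artifact under the output directory and finishes with a
manifest JSON (config hash, seeds, per-stage wall time, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .lacunarity import AssayDescriptors, compute_descriptors
from .optics import LedGridSpec, OpticalSystem, build_led_geometry, make_pupil
from .recon import ReconConfig, extract_phase_map, reconstruct
from .simulate import (NoiseSpec, SceneSpec, add_noise, forward_acquire,
                       hr_grid, synth_diatom_scene)
from .texture import GlcmSpec, range_glcm_entropy
from . import io as fio

__all__ = ["RunConfig", "run_pipeline", "simulate_descriptors"]


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    optics: OpticalSystem = field(default_factory=lambda: OpticalSystem(
        wavelength_um=0.52, na_mo=0.25, magnification=4.0,
        pixel_pitch_um=2.0, grid_size=128))
    leds: LedGridSpec = field(default_factory=lambda: LedGridSpec(
        rows=5, cols=5, pitch_mm=6.0, height_mm=70.0))
    scene: SceneSpec = field(default_factory=SceneSpec)
    recon: ReconConfig = field(default_factory=ReconConfig)
    noise: NoiseSpec | None = None
    glcm: GlcmSpec = field(default_factory=GlcmSpec)
    binarize_method: str = "otsu"
    binarize_param: float | None = None
    r_local: int | None = None
    flatten_phase: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise"] = None if self.noise is None else asdict(self.noise)
        d["glcm"]["angles"] = list(self.glcm.angles)
        d["glcm"]["percentile_range"] = list(self.glcm.percentile_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["optics"] = OpticalSystem(**d["optics"])
        d["leds"] = LedGridSpec(**d["leds"])
        d["scene"] = SceneSpec(**d["scene"])
        d["recon"] = ReconConfig(**d["recon"])
        d["noise"] = NoiseSpec(**d["noise"]) if d.get("noise") else None
        if "glcm" in d:
            g = dict(d["glcm"])
            g["angles"] = tuple(g.get("angles", GlcmSpec().angles))
            g["percentile_range"] = tuple(
                g.get("percentile_range", GlcmSpec().percentile_range))
            if g.get("phase_range") is not None:
                g["phase_range"] = tuple(g["phase_range"])
            d["glcm"] = GlcmSpec(**g)
        return cls(**d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def child_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        scene_s, noise_s = ss.spawn(2)
        return {"scene": int(scene_s.generate_state(1)[0] % (2**31)),
                "noise": int(noise_s.generate_state(1)[0] % (2**31))}


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 fov_id: str = "fov0") -> AssayDescriptors:
    """Simulate, acquire, reconstruct and analyze one field of view.

    Writes the ground-truth field, the intensity stack, the reconstruction,
    the descriptor CSV row and a manifest JSON under ``out_dir``; refuses to
    overwrite an existing manifest.  Deterministic for a fixed config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        raise FileExistsError(f"{manifest_path} exists; refusing to "
                              "overwrite a completed run")
    seeds = config.child_seeds()
    stages: dict[str, float] = {}
    manifest = {"package_version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed, "child_seeds": seeds,
                "stages_completed": [], "stage_seconds": stages}

    def _finish_stage(name: str, t0: float) -> None:
        stages[name] = round(time.perf_counter() - t0, 3)
        manifest["stages_completed"].append(name)

    try:
        t0 = time.perf_counter()
        geom = build_led_geometry(config.leds, config.optics)
        shape, hr_pixel = hr_grid(config.optics, geom)
        scene_spec = dataclasses.replace(config.scene, seed=seeds["scene"])
        truth = synth_diatom_scene(scene_spec, shape, hr_pixel)
        fio.write_field(truth, out, stem="ground_truth")
        _finish_stage("simulate", t0)

        t0 = time.perf_counter()
        pupil = make_pupil(config.optics)
        stack = forward_acquire(truth, pupil, geom, config.optics)
        if config.noise is not None:
            stack = add_noise(stack, config.noise, seeds["noise"])
        fio.write_stack(stack, out / "stack.tif")
        _finish_stage("acquire", t0)

        t0 = time.perf_counter()
        recfield, recpupil, misfits = reconstruct(stack, geom, config.optics,
                                                  config.recon)
        fio.write_field(recfield, out, stem="reconstruction")
        np.savetxt(out / "misfit_history.csv",
                   np.column_stack([np.arange(1, len(misfits) + 1), misfits]),
                   delimiter=",", header="outer_loop,relative_misfit",
                   comments="")
        _finish_stage("reconstruct", t0)

        t0 = time.perf_counter()
        pmap = extract_phase_map(recfield, flatten=config.flatten_phase)
        desc = compute_descriptors(pmap, method=config.binarize_method,
                                   param=config.binarize_param,
                                   r_local=config.r_local, fov_id=fov_id,
                                   exposure=config.scene.exposure)
        desc.delta_s_bits = range_glcm_entropy(pmap, config.glcm)
        fio.write_descriptors([desc], out / "descriptors.csv")
        _finish_stage("analyze", t0)
    finally:
        config.save(out / "config.yaml")
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return desc


def simulate_descriptors(config: RunConfig, fov_id: str = "fov0",
                         reconstruct_field: bool = True,
                         dose_um: float | None = None) -> AssayDescriptors:
    """In-memory variant of :func:`run_pipeline` (no files written).

    With ``reconstruct_field=False`` the descriptors are computed on the
    ground-truth phase map, which is useful for fast descriptor studies.
    """
    seeds = config.child_seeds()
    geom = build_led_geometry(config.leds, config.optics)
    shape, hr_pixel = hr_grid(config.optics, geom)
    scene_spec = dataclasses.replace(config.scene, seed=seeds["scene"])
    truth = synth_diatom_scene(scene_spec, shape, hr_pixel)
    if reconstruct_field:
        pupil = make_pupil(config.optics)
        stack = forward_acquire(truth, pupil, geom, config.optics)
        if config.noise is not None:
            stack = add_noise(stack, config.noise, seeds["noise"])
        recfield, _, _ = reconstruct(stack, geom, config.optics, config.recon)
        pmap = extract_phase_map(recfield, flatten=config.flatten_phase)
    else:
        pmap = extract_phase_map(truth, flatten=False)
    desc = compute_descriptors(pmap, method=config.binarize_method,
                               param=config.binarize_param,
                               r_local=config.r_local, fov_id=fov_id,
                               exposure=config.scene.exposure,
                               dose_um=dose_um)
    desc.delta_s_bits = range_glcm_entropy(pmap, config.glcm)
    return desc
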