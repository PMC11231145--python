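"""File formats: TIFF stacks with YAML sidecars, field maps, CSV, model JSON.

Intensity stacks are stored as multi-page 16-bit TIFFs with a recorded
intensity scale factor; geometry and optics travel in a YAML sidecar next to
the stack.  Reconstructed fields are written as 32-bit float amplitude and
phase TIFFs with a JSON metadata file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .assay import CalibrationModel
from .lacunarity import AssayDescriptors
from .optics import LedGeometry, LedGridSpec, OpticalSystem
from .recon import PhaseMap
from .simulate import HighResField, IntensityStack

__all__ = [
    "write_stack", "read_stack",
    "write_field", "read_phase_map",
    "descriptors_to_frame", "write_descriptors", "read_descriptors",
    "write_model", "read_model",
]

_SCALE_BITS = 65535


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _optics_to_dict(o: OpticalSystem) -> dict:
    return {"wavelength_um": o.wavelength_um, "na_mo": o.na_mo,
            "magnification": o.magnification,
            "pixel_pitch_um": o.pixel_pitch_um, "grid_size": o.grid_size}


def _geometry_to_dict(g: LedGeometry) -> dict:
    d: dict = {"freqs_cyc_per_um": np.asarray(g.freqs_cyc_per_um).tolist()}
    if g.grid_spec is not None:
        s = g.grid_spec
        d["grid_spec"] = {"rows": s.rows, "cols": s.cols,
                          "pitch_mm": s.pitch_mm, "height_mm": s.height_mm,
                          "keep_radius": s.keep_radius}
    return d


def _geometry_from_dict(d: dict) -> LedGeometry:
    spec = None
    if d.get("grid_spec"):
        spec = LedGridSpec(**d["grid_spec"])
    return LedGeometry(freqs_cyc_per_um=np.asarray(d["freqs_cyc_per_um"]),
                       grid_spec=spec)


def write_stack(stack: IntensityStack, path: str | Path) -> Path:
    """Write a stack as 16-bit multi-page TIFF plus a YAML sidecar."""
    path = Path(path)
    peak = float(stack.images.max())
    scale = peak / _SCALE_BITS if peak > 0 else 1.0
    pages = np.round(stack.images / scale).astype(np.uint16)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "intensity_scale": scale,
        "optics": _optics_to_dict(stack.optics),
        "geometry": _geometry_to_dict(stack.geometry),
        "noise": stack.noise,
        "meta": {k: v for k, v in stack.meta.items()
                 if isinstance(v, (int, float, str, bool))},
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def read_stack(path: str | Path) -> IntensityStack:
    """Load a stack and its sidecar; page count must match the geometry."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    sidecar = yaml.safe_load(sidecar_file.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    geometry = _geometry_from_dict(sidecar["geometry"])
    if pages.shape[0] != geometry.n_leds:
        raise ValueError(f"stack {path} has {pages.shape[0]} pages but the "
                         f"sidecar geometry lists {geometry.n_leds} LEDs")
    optics = OpticalSystem(**sidecar["optics"])
    images = pages.astype(float) * float(sidecar["intensity_scale"])
    return IntensityStack(images=images, geometry=geometry, optics=optics,
                          noise=sidecar.get("noise") or {},
                          meta=sidecar.get("meta") or {})


def write_field(fieldobj: HighResField, out_dir: str | Path,
                stem: str = "field") -> dict[str, Path]:
    """Write amplitude/phase float32 TIFFs and a JSON metadata file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "amplitude": out / f"{stem}_amplitude.tif",
        "phase": out / f"{stem}_phase.tif",
        "meta": out / f"{stem}_meta.json",
    }
    tifffile.imwrite(paths["amplitude"],
                     fieldobj.amplitude.astype(np.float32))
    tifffile.imwrite(paths["phase"], fieldobj.phase.astype(np.float32))
    meta = {"pixel_um": fieldobj.pixel_um, "provenance": fieldobj.provenance,
            **{k: v for k, v in fieldobj.meta.items()
               if isinstance(v, (int, float, str, bool))}}
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths


def read_phase_map(phase_tif: str | Path,
                   pixel_um: float | None = None) -> PhaseMap:
    """Load a 32-bit float phase TIFF (pitch from the sibling JSON if any)."""
    phase_tif = Path(phase_tif)
    values = tifffile.imread(phase_tif).astype(float)
    if pixel_um is None:
        meta_file = phase_tif.with_name(
            phase_tif.name.replace("_phase.tif", "_meta.json"))
        if meta_file.exists():
            pixel_um = float(json.loads(meta_file.read_text())["pixel_um"])
        else:
            raise ValueError("pixel pitch not given and no metadata file "
                             f"next to {phase_tif}")
    return PhaseMap(values=values, pixel_um=pixel_um)


_DESCRIPTOR_COLUMNS = ["fov_id", "exposure", "dose_uM", "GL", "LL",
                       "r_local_um", "MSL", "delta_s_bits"]


def descriptors_to_frame(rows: list[AssayDescriptors]) -> pd.DataFrame:
    recs = [{"fov_id": r.fov_id, "exposure": r.exposure, "dose_uM": r.dose_um,
             "GL": r.gl, "LL": r.ll, "r_local_um": r.r_local_um,
             "MSL": r.msl, "delta_s_bits": r.delta_s_bits} for r in rows]
    return pd.DataFrame(recs, columns=_DESCRIPTOR_COLUMNS)


def write_descriptors(rows: list[AssayDescriptors],
                      path: str | Path) -> Path:
    path = Path(path)
    descriptors_to_frame(rows).to_csv(path, index=False)
    return path


def read_descriptors(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_model(model: CalibrationModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(model.to_dict(), indent=2))
    return path


def read_model(path: str | Path) -> CalibrationModel:
    return CalibrationModel.from_dict(json.loads(Path(path).read_text()))
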