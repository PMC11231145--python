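"""Gliding-box lacunarity and the multi-scale descriptors GL, LL, MSL.

Lacunarity quantifies the gappiness of a binary occupancy set.  For a box
side r, slide an r×r box over every fully-inside position (unit step), count
the occupied pixels m in each box, and form the ratio of moments

    Λ(r) = E[m²] / E[m]²  (Allain–Cloitre gliding box),

which is 1 for a translation-invariant full mask and grows with the
heterogeneity of the hole-size distribution at scale r.  Three scalar
descriptors summarize a phase-contrast map:

* ``GL`` — global lacunarity, the geometric mean of Λ(r) over a dyadic scale
  ladder; an ensemble descriptor of hole sizes across scales, from the
  diatom interior to the whole-population arrangement.
* ``LL`` — local lacunarity, Λ at a single scale matched to the diatom size,
  probing only the cell-to-medium interplay.
* ``MSL = GL / LL`` — the multi-scale lacunarity dose descriptor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .recon import PhaseMap

__all__ = [
    "BinaryMask",
    "LacunarityProfile",
    "AssayDescriptors",
    "binarize_phase",
    "box_masses",
    "gliding_box_lacunarity",
    "global_lacunarity",
    "local_lacunarity",
    "select_local_scale",
    "multi_scale_lacunarity",
    "dyadic_scales",
    "compute_descriptors",
]


@dataclass
class BinaryMask:
    """Object-occupancy mask derived from a phase map."""

    values: np.ndarray
    pixel_um: float
    method: str = "otsu"
    threshold: float | None = None
    component_diameters_um: np.ndarray = field(
        default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def occupancy(self) -> float:
        return float(self.values.mean())


@dataclass
class LacunarityProfile:
    """Λ(r) over an ascending list of box sizes (pixels)."""

    scales: np.ndarray
    lacunarity: np.ndarray
    pixel_um: float = 1.0
    algorithm: str = "gliding-box"

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        self.lacunarity = np.asarray(self.lacunarity, dtype=float)
        if self.scales.shape != self.lacunarity.shape:
            raise ValueError("scales and values must align")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly ascending")

    @property
    def scales_um(self) -> np.ndarray:
        return self.scales * self.pixel_um


@dataclass
class AssayDescriptors:
    """Per-field-of-view descriptor row of the dose assay."""

    gl: float
    ll: float
    msl: float
    r_local_um: float
    delta_s_bits: float | None = None
    fov_id: str = ""
    exposure: str = "T3"
    dose_um: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gl) and np.isfinite(self.ll)
                and np.isfinite(self.msl)):
            raise ValueError("descriptors must be finite")
        if self.msl <= 0:
            raise ValueError("MSL must be positive")
        if abs(self.msl - self.gl / self.ll) > 1e-9 * max(1.0, self.msl):
            raise ValueError("MSL must equal GL/LL")


def binarize_phase(pmap: PhaseMap, method: str = "otsu",
                   param: float | None = None) -> BinaryMask:
    """Threshold a phase map into an object mask.

    ``method="otsu"`` uses Otsu's threshold on the phase values (default);
    ``method="fixed"`` thresholds at ``param`` rad.  Connected-component
    equivalent diameters (µm) are recorded for local-scale selection.
    """
    phase = pmap.values
    if method == "otsu":
        if np.ptp(phase) == 0:
            thr = float(phase.flat[0])
            mask = np.zeros(phase.shape, dtype=bool)
        else:
            thr = float(threshold_otsu(phase))
            mask = phase > thr
    elif method == "fixed":
        if param is None:
            raise ValueError("fixed-threshold binarization needs a value")
        thr = float(param)
        mask = phase > thr
    else:
        raise ValueError(f"unknown binarization method {method!r}")

    if mask.all() or not mask.any():
        warnings.warn("binarization produced an all-%s mask"
                      % ("object" if mask.all() else "background"),
                      stacklevel=2)
    labels = label(mask)
    diams = np.array([p.equivalent_diameter_area
                      for p in regionprops(labels)])
    return BinaryMask(values=mask, pixel_um=pmap.pixel_um, method=method,
                      threshold=thr,
                      component_diameters_um=diams * pmap.pixel_um)


def box_masses(mask: np.ndarray, r: int) -> np.ndarray:
    """Occupied-pixel counts of every fully-inside r×r gliding box."""
    m = np.asarray(mask, dtype=np.int64)
    if r < 1 or r > min(m.shape):
        raise ValueError(f"box size {r} outside [1, {min(m.shape)}]")
    S = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(m, axis=0), axis=1, out=S[1:, 1:])
    return (S[r:, r:] - S[:-r, r:] - S[r:, :-r] + S[:-r, :-r])


def _lambda_at(mask: np.ndarray, r: int) -> float:
    masses = box_masses(mask, r).ravel()
    mean = masses.mean()
    if mean == 0:
        raise ValueError(f"empty mask at scale {r}: lacunarity undefined")
    return float(np.mean(masses.astype(float) ** 2) / mean**2)


def dyadic_scales(shape: tuple[int, int], r_max: int | None = None
                  ) -> list[int]:
    """Default scale ladder {2, 4, 8, …} up to half the smaller image side."""
    limit = min(shape) // 2 if r_max is None else r_max
    scales, r = [], 2
    while r <= limit:
        scales.append(r)
        r *= 2
    if not scales:
        raise ValueError("image too small for the dyadic scale ladder")
    return scales


def gliding_box_lacunarity(mask: BinaryMask,
                           scales: list[int] | None = None
                           ) -> LacunarityProfile:
    """Λ(r) = E[m²]/E[m]² over fully-inside gliding boxes at each scale."""
    m = mask.values
    if scales is None:
        scales = dyadic_scales(m.shape)
    scales = sorted(int(s) for s in scales)
    vals = [_lambda_at(m, r) for r in scales]
    return LacunarityProfile(scales=np.asarray(scales),
                             lacunarity=np.asarray(vals),
                             pixel_um=mask.pixel_um)


def global_lacunarity(profile: LacunarityProfile,
                      aggregation: str = "geometric") -> float:
    """Ensemble lacunarity across the scale ladder.

    Λ spans decades between small and large boxes, so the default summary is
    the geometric mean, exp(mean ln Λ(r)); an arithmetic mean and the log-log
    slope of Λ(r) are available as alternatives.
    """
    lam = profile.lacunarity
    if lam.size < 2:
        raise ValueError("global lacunarity needs at least two scales")
    if np.any(lam <= 0):
        raise ValueError("lacunarity values must be positive")
    if aggregation == "geometric":
        return float(np.exp(np.mean(np.log(lam))))
    if aggregation == "arithmetic":
        return float(np.mean(lam))
    if aggregation == "slope":
        coef = np.polyfit(np.log(profile.scales), np.log(lam), 1)
        return float(coef[0])
    raise ValueError(f"unknown aggregation {aggregation!r}")


def local_lacunarity(mask: BinaryMask, r_local: int) -> float:
    """Λ at the single, diatom-sized scale ``r_local`` (pixels)."""
    return _lambda_at(mask.values, int(r_local))


def select_local_scale(mask: BinaryMask) -> int:
    """Diatom-sized box from the mask's components.

    The median equivalent diameter of the connected components, rounded,
    clamped into [2, min(dims)/4].
    """
    if mask.component_diameters_um.size == 0:
        raise ValueError("empty mask: pass an explicit local scale")
    med_px = np.median(mask.component_diameters_um) / mask.pixel_um
    hi = max(2, min(mask.values.shape) // 4)
    return int(np.clip(round(med_px), 2, hi))


def multi_scale_lacunarity(gl: float, ll: float) -> float:
    """MSL = GL / LL, the ratio of global to local lacunarity."""
    if gl <= 0 or ll <= 0:
        raise ValueError("GL and LL must be positive")
    return gl / ll


def compute_descriptors(pmap: PhaseMap, method: str = "otsu",
                        param: float | None = None,
                        scales: list[int] | None = None,
                        r_local: int | None = None,
                        fov_id: str = "", exposure: str = "T3",
                        dose_um: float | None = None) -> AssayDescriptors:
    """Full lacunarity descriptor set of one phase-contrast map."""
    mask = binarize_phase(pmap, method=method, param=param)
    profile = gliding_box_lacunarity(mask, scales=scales)
    gl = global_lacunarity(profile)
    r = select_local_scale(mask) if r_local is None else int(r_local)
    ll = local_lacunarity(mask, r)
    msl = multi_scale_lacunarity(gl, ll)
    return AssayDescriptors(gl=gl, ll=ll, msl=msl,
                            r_local_um=r * pmap.pixel_um, fov_id=fov_id,
                            exposure=exposure, dose_um=dose_um)
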