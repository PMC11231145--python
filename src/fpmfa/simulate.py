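"""Synthetic diatom scenes and the ptychographic forward model.

The scene generator emulates thin films of chain-forming diatoms
(*Skeletonema*-like: short chains of elliptical frustules a few µm across)
as pure-phase objects, |o(r)| = 1.  A stress severity s ∈ [0, 1] drives the
dose-dependent morphological damage observed under copper exposure:

* a growing fraction of cells undergoes membrane lysis,
* lysed cells extrude cytoplasm, adding low-phase leak blobs around the
  chain (leaked area fraction increases monotonically with s),
* chains fragment into shorter pieces,
* the mean per-cell peak phase drops (thinner, degraded frustules).

The forward model synthesizes what the FPM microscope records for each LED:
``I_n(r) = |IFT{ O(ν − ν_n) · P(ν) }|²`` evaluated by shifting the
high-resolution spectrum by the nearest spectral sample to ν_n, multiplying
by the pupil on the low-resolution window and inverse transforming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._fft import fft2c, ifft2c, window_slices
from .optics import LedGeometry, OpticalSystem, Pupil

__all__ = [
    "SceneSpec",
    "HighResField",
    "IntensityStack",
    "NoiseSpec",
    "upsampling_factor",
    "hr_grid",
    "severity_from_dose",
    "synth_diatom_scene",
    "two_point_target",
    "forward_acquire",
    "add_noise",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class HighResField:
    """Complex field o(r) on the up-sampled grid."""

    data: np.ndarray
    pixel_um: float
    provenance: str = "simulated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("field must be 2-D")
        if self.pixel_um <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def spectrum(self) -> np.ndarray:
        """Centered Fourier spectrum O(ν) of o(r)."""
        return fft2c(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)


@dataclass
class IntensityStack:
    """N low-resolution intensity images with their acquisition geometry."""

    images: np.ndarray  # (N, n, n) real, non-negative
    geometry: LedGeometry
    optics: OpticalSystem
    noise: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("stack must be (N, ny, nx)")
        if self.images.shape[0] != self.geometry.n_leds:
            raise ValueError(
                f"stack has {self.images.shape[0]} pages but geometry lists "
                f"{self.geometry.n_leds} LEDs")
        if np.any(self.images < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]


@dataclass(frozen=True)
class NoiseSpec:
    """Detection noise: shot noise at ``photons_per_unit`` intensity-1 photons
    plus additive Gaussian read noise of ``read_sigma`` (intensity units)."""

    photons_per_unit: float | None = 10_000.0
    read_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.photons_per_unit is not None and self.photons_per_unit <= 0:
            raise ValueError("photon budget must be positive (or None)")
        if self.read_sigma < 0:
            raise ValueError("read-noise sigma must be non-negative")


# ---------------------------------------------------------------------------
# scene synthesis


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic diatom field of view.

    ``density_per_mm2`` is the areal cell density.  The experimental samples
    this emulates were concentrated to ~190,000 cells/ml and imaged as a thin
    settled film; :func:`areal_density_from_cells_per_ml` converts a volume
    density and film thickness to the areal value.  Miniature test fields use
    a higher density so that a field still holds tens of cells.
    """

    density_per_mm2: float = 2000.0
    chain_len_mean: float = 4.0
    cell_minor_um: float = 4.0
    cell_major_um: float = 7.0
    peak_phase_rad: float = 1.2
    stress: float = 0.0
    exposure: str = "T3"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_per_mm2 < 0:
            raise ValueError("density must be non-negative")
        if not 0.0 <= self.stress <= 1.0:
            raise ValueError("stress severity must lie in [0, 1]")
        if self.cell_minor_um <= 0 or self.cell_major_um <= 0:
            raise ValueError("cell axes must be positive")
        if self.chain_len_mean < 1:
            raise ValueError("mean chain length must be >= 1")


def areal_density_from_cells_per_ml(cells_per_ml: float,
                                    film_um: float) -> float:
    """Cells/mm² of a settled film of given thickness (µm)."""
    return cells_per_ml * (film_um * 1e-4) / 100.0  # cells/cm³ · cm → /cm² → /mm²


def severity_from_dose(dose_um: float, exposure: str = "T3") -> float:
    """Map a Cu dose (µM) and exposure time to a stress severity in [0, 1].

    Longer exposure internalizes more copper, so the 72 h series (T3) damages
    the population roughly twice as fast per µM as the 48 h series (T2); both
    share severity 0 at dose 0 (negative control).
    """
    if dose_um < 0:
        raise ValueError("dose must be non-negative")
    scale = {"T2": 110.0, "T3": 55.0}
    try:
        return min(1.0, dose_um / scale[exposure])
    except KeyError:
        raise ValueError(f"unknown exposure tag {exposure!r} (use T2 or T3)")


def _phase_bump(shape, cy, cx, a_px, b_px, theta, peak):
    """Raised-cosine elliptical phase footprint; returns (patch, sy, sx)."""
    r = int(math.ceil(max(a_px, b_px))) + 1
    y0, y1 = max(0, int(cy) - r), min(shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(shape[1], int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    rho2 = (u / a_px) ** 2 + (v / b_px) ** 2
    patch = np.where(rho2 < 1.0, peak * 0.5 * (1 + np.cos(np.pi * np.sqrt(
        np.clip(rho2, 0, 1)))), 0.0)
    return patch, slice(y0, y1), slice(x0, x1)


def synth_diatom_scene(spec: SceneSpec, shape: tuple[int, int],
                       pixel_um: float) -> HighResField:
    """Render a pure-phase diatom scene on the given high-resolution grid.

    Returns a :class:`HighResField` with ``meta`` carrying the ground truth:
    ``cell_mask``, ``leak_mask``, ``n_cells``, ``n_lysed``, per-cell peak
    phases and the achieved areal density.  Deterministic under a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = shape
    area_mm2 = (ny * pixel_um * 1e-3) * (nx * pixel_um * 1e-3)
    n_cells_target = int(round(spec.density_per_mm2 * area_mm2))

    phase = np.zeros(shape, dtype=float)
    cell_mask = np.zeros(shape, dtype=bool)
    leak_mask = np.zeros(shape, dtype=bool)

    # dose–response of the damage is concave in the severity (steep at low
    # doses, saturating at high doses, as sigmoidal toxicity curves are)
    sev = spec.stress ** 0.6
    a_px = 0.5 * spec.cell_major_um / pixel_um   # semi-major, px
    b_px = 0.5 * spec.cell_minor_um / pixel_um   # semi-minor, px
    # chain fragmentation shortens chains as stress rises
    eff_chain_mean = max(1.0, spec.chain_len_mean * (1.0 - 0.6 * sev))

    p_lyse = 0.85 * sev
    placed = 0
    centers: list[tuple[float, float]] = []
    tries = 0
    max_tries = 400 * max(1, n_cells_target)
    cells: list[tuple[float, float, float]] = []  # (cy, cx, theta)
    len_carry = 0.0

    while placed < n_cells_target:
        if tries > max_tries:
            achieved = placed / area_mm2 if area_mm2 > 0 else 0.0
            raise RuntimeError(
                f"scene placement failed: achieved density {achieved:.0f}"
                f"/mm² of requested {spec.density_per_mm2:.0f}/mm²")
        tries += 1
        # chain lengths follow the mean via remainder carry (stratified, see
        # the orientation note below)
        chain_len = min(max(1, int(eff_chain_mean + len_carry)),
                        n_cells_target - placed)
        # stratified (golden-ratio) chain orientations: a miniature field
        # holds few chains, so uniform draws would leave spurious net
        # anisotropy that a full-size field of thousands of diatoms lacks
        theta = math.pi * ((len(centers) * 0.6180339887498949
                            + rng.uniform(-0.02, 0.02)) % 1.0)
        step = 1.9 * b_px  # cells abut along the chain (pervalvar) axis
        half = 0.5 * (chain_len - 1) * step
        cy = rng.uniform(0, ny)
        cx = rng.uniform(0, nx)
        # keep the whole chain inside the field, reject crowded placements
        end_y = abs(half * math.cos(theta)) + a_px
        end_x = abs(half * math.sin(theta)) + a_px
        if cy - end_y < 0 or cy + end_y > ny or cx - end_x < 0 or cx + end_x > nx:
            continue
        min_sep = 2.2 * a_px
        if any((cy - py) ** 2 + (cx - px_) ** 2 < min_sep**2
               for py, px_ in centers):
            continue
        centers.append((cy, cx))
        len_carry += eff_chain_mean - chain_len
        for k in range(chain_len):
            off = -half + k * step
            cells.append((cy + off * math.cos(theta),
                          cx + off * math.sin(theta), theta))
            placed += 1

    # population-level damage: the lysed fraction of a dosed culture is a
    # property of the whole sample, so exactly round(p·n) cells lyse (a
    # miniature field would otherwise carry binomial noise that a full-size
    # field of thousands of cells averages away)
    n_lysed = int(round(p_lyse * len(cells)))
    lysed_idx = set(rng.choice(len(cells), size=n_lysed, replace=False)
                    ) if n_lysed else set()

    cell_peaks: list[float] = []
    pending_lysed: list[tuple[float, float]] = []
    for i, (ccy, ccx, theta) in enumerate(cells):
        lysed = i in lysed_idx
        peak = spec.peak_phase_rad * (1.0 - 0.45 * sev) \
            * rng.lognormal(0.0, 0.12)
        if lysed:
            peak *= 0.55
            pending_lysed.append((ccy, ccx))
        # frustule axes: chain (pervalvar) axis along theta → the cell's
        # long valvar axis lies across the chain
        res = _phase_bump(shape, ccy, ccx, b_px, a_px, theta, peak)
        if res is not None:
            patch, sy, sx = res
            phase[sy, sx] += patch
            cell_mask[sy, sx] |= patch > 0.25 * peak
        cell_peaks.append(peak)

    # cytoplasm leaks: low-phase blobs scattered around lysed cells; the
    # per-cell blob count follows the mean exactly via remainder carry and
    # the blob bearings are golden-angle stratified (miniature-field
    # variance correction, as for orientations and the lysed fraction)
    mean_blobs = 3.0 + 4.0 * sev
    blob_carry = 0.0
    for ccy, ccx in pending_lysed:
        blob_carry += mean_blobs
        n_blobs = int(blob_carry)
        blob_carry -= n_blobs
        ang0 = rng.uniform(0, 2 * math.pi)
        for j in range(n_blobs):
            ang = ang0 + 2 * math.pi * ((j * 0.6180339887498949) % 1.0)
            dist = rng.uniform(0.8, 2.5 + 2.0 * sev) * b_px
            by = ccy + dist * math.cos(ang)
            bx = ccx + dist * math.sin(ang)
            br = rng.uniform(0.3, 0.8) * b_px
            bpeak = rng.uniform(0.25, 0.5)
            res = _phase_bump(shape, by, bx, br, br, 0.0, bpeak)
            if res is not None:
                patch, sy, sx = res
                phase[sy, sx] += patch
                leak_mask[sy, sx] |= patch > 0.25 * bpeak

    meta = {
        "spec": spec,
        "cell_mask": cell_mask,
        "leak_mask": leak_mask,
        "n_cells": placed,
        "n_lysed": n_lysed,
        "cell_peaks_rad": np.asarray(cell_peaks),
        "achieved_density_per_mm2": placed / area_mm2 if area_mm2 else 0.0,
    }
    return HighResField(data=np.exp(1j * phase), pixel_um=pixel_um,
                        provenance="simulated", meta=meta)


def two_point_target(shape: tuple[int, int], pixel_um: float,
                     separation_um: float, point_fwhm_um: float,
                     phase_step_rad: float = math.pi / 2,
                     background: float = 0.05) -> HighResField:
    """Two point-like scatterers for resolution tests, separated along x.

    Each point is a Gaussian bump of the given FWHM added to a dim uniform
    background; the second point carries a ``phase_step_rad`` offset
    (quadrature by default, so the two point images add incoherently and the
    classical two-point resolution criterion applies to the coherent
    reconstruction as well).
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    cy, cx = ny / 2.0, nx / 2.0
    half = 0.5 * separation_um / pixel_um
    sigma = point_fwhm_um / pixel_um / 2.3548
    field = np.full(shape, background, dtype=complex)
    for dx, ph in ((-half, 0.0), (half, phase_step_rad)):
        field += np.exp(1j * ph) * np.exp(
            -((yy - cy) ** 2 + (xx - cx - dx) ** 2) / (2 * sigma**2))
    return HighResField(data=field, pixel_um=pixel_um, provenance="simulated",
                        meta={"separation_um": separation_um})


# ---------------------------------------------------------------------------
# forward acquisition


def upsampling_factor(optics: OpticalSystem, geom: LedGeometry) -> int:
    """High-res/low-res grid ratio covering the synthetic aperture.

    ``ceil((NA_MO + λ·max|ν_n|) / NA_MO)`` rounded up to an even integer, so
    the up-sampled spectrum holds every shifted pupil window.
    """
    na_syn = optics.na_mo + optics.wavelength_um * geom.max_frequency()
    u = math.ceil(na_syn / optics.na_mo)
    return u + (u % 2)


def hr_grid(optics: OpticalSystem, geom: LedGeometry) -> tuple[tuple[int, int], float]:
    """Shape and pixel pitch (µm) of the high-resolution grid."""
    u = upsampling_factor(optics, geom)
    n = optics.grid_size * u
    return (n, n), optics.sample_pitch_um / u


def shift_samples(geom: LedGeometry, optics: OpticalSystem) -> np.ndarray:
    """Illumination shifts ν_n rounded to integer spectral samples, (N, 2)."""
    return np.rint(geom.freqs_cyc_per_um
                   / optics.freq_step_cyc_per_um).astype(int)


def forward_acquire(fieldobj: HighResField, pupil: Pupil, geom: LedGeometry,
                    optics: OpticalSystem) -> IntensityStack:
    """Simulate the low-resolution intensity stack recorded by the microscope.

    For each LED n the high-resolution spectrum is shifted by the nearest
    spectral sample to ν_n, multiplied by the pupil over the low-resolution
    window, inverse transformed and squared:
    ``I_n = |IFT{O(ν − ν_n) P(ν)}|²``.
    """
    n_lr = optics.grid_size
    n_hr = fieldobj.shape[0]
    if fieldobj.shape[0] != fieldobj.shape[1]:
        raise ValueError("high-resolution field must be square")
    if n_hr % n_lr != 0:
        raise ValueError("field grid must be an integer multiple of the "
                         "detector grid")
    O = fieldobj.spectrum()
    shifts = shift_samples(geom, optics)
    images = np.empty((geom.n_leds, n_lr, n_lr))
    for i, (sy, sx) in enumerate(shifts):
        try:
            win = window_slices((n_hr, n_hr), (n_lr, n_lr), (-sy, -sx))
        except ValueError as exc:
            raise ValueError(
                f"LED {i} (ν = {geom.freqs_cyc_per_um[i]} cycles/µm) shifts "
                f"the spectrum outside its support") from exc
        phi = O[win] * pupil.values
        Phi = ifft2c(phi)
        images[i] = np.abs(Phi) ** 2
    meta = {"upsampling": n_hr // n_lr, "hr_pixel_um": fieldobj.pixel_um}
    return IntensityStack(images=images, geometry=geom, optics=optics,
                          meta=meta)


def add_noise(stack: IntensityStack, noise: NoiseSpec,
              seed: int) -> IntensityStack:
    """Apply shot noise then read noise to a stack; clipped at zero."""
    rng = np.random.default_rng(seed)
    images = stack.images
    if noise.photons_per_unit is not None and np.isfinite(noise.photons_per_unit):
        b = noise.photons_per_unit
        images = rng.poisson(np.clip(images, 0, None) * b) / b
    if noise.read_sigma > 0:
        images = images + rng.normal(0.0, noise.read_sigma, images.shape)
    images = np.clip(images, 0.0, None)
    return IntensityStack(images=images, geometry=stack.geometry,
                          optics=stack.optics,
                          noise={"photons_per_unit": noise.photons_per_unit,
                                 "read_sigma": noise.read_sigma, "seed": seed},
                          meta=dict(stack.meta))
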