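"""Optical system description, LED-array illumination geometry and pupils.

An LED at lateral position (x, y) a height ``h`` below the sample illuminates
it with a plane wave whose spatial carrier frequency is
``nu = (sin(theta_x), sin(theta_y)) / lambda`` with
``sin(theta) = offset / sqrt(x^2 + y^2 + h^2)``.  The objective acts as a
low-pass filter with a circular pupil of radius ``NA_MO / lambda`` in the
frequency plane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalSystem",
    "LedGridSpec",
    "LedGeometry",
    "build_led_geometry",
    "disk_radius_for_count",
    "Pupil",
    "make_pupil",
    "defocus_phase",
]


@dataclass(frozen=True)
class OpticalSystem:
    """Imaging-side parameters of the microscope.

    Parameters
    ----------
    wavelength_um : float
        Central illumination wavelength (µm).
    na_mo : float
        Numerical aperture of the microscope objective, in (0, 1).
    magnification : float
        Objective magnification (detector pixel → sample pixel scale).
    pixel_pitch_um : float
        Detector pixel pitch (µm); the sample-plane pitch is
        ``pixel_pitch_um / magnification``.
    grid_size : int
        Side length of the (square) low-resolution detector crop, pixels.
    """

    wavelength_um: float
    na_mo: float
    magnification: float
    pixel_pitch_um: float
    grid_size: int

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.na_mo < 1:
            raise ValueError("NA_MO must lie in (0, 1)")
        if self.magnification <= 0 or self.pixel_pitch_um <= 0:
            raise ValueError("magnification and pixel pitch must be positive")
        if self.grid_size < 2:
            raise ValueError("grid size must be at least 2")
        if self.pupil_radius_samples(self.grid_size) < 1.0:
            raise ValueError(
                "pupil diameter spans fewer than 2 spectral samples; "
                "increase grid size or NA")

    @property
    def sample_pitch_um(self) -> float:
        """Low-resolution pixel pitch referred to the sample plane (µm)."""
        return self.pixel_pitch_um / self.magnification

    @property
    def cutoff_cyc_per_um(self) -> float:
        """Coherent cutoff frequency of the objective, NA_MO/λ (cycles/µm)."""
        return self.na_mo / self.wavelength_um

    @property
    def freq_step_cyc_per_um(self) -> float:
        """Spectral sample spacing of the low-resolution grid (cycles/µm)."""
        return 1.0 / (self.grid_size * self.sample_pitch_um)

    def pupil_radius_samples(self, grid_size: int | None = None) -> float:
        """Pupil radius in spectral samples on an ``grid_size`` grid."""
        n = self.grid_size if grid_size is None else grid_size
        return self.cutoff_cyc_per_um * n * self.sample_pitch_um


@dataclass(frozen=True)
class LedGridSpec:
    """Rectangular LED matrix: ``rows x cols`` LEDs at ``pitch_mm`` spacing,
    ``height_mm`` below the sample, optionally truncated to a disk of
    ``keep_radius`` (in LED-index units) around the central LED."""

    rows: int = 15
    cols: int = 15
    pitch_mm: float = 4.0
    height_mm: float = 67.0
    keep_radius: float | None = None

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("LED grid must contain at least one LED")
        if self.pitch_mm <= 0 or self.height_mm <= 0:
            raise ValueError("LED pitch and height must be positive")


@dataclass(frozen=True)
class LedGeometry:
    """Ordered illumination frequencies of the LED array.

    ``freqs_cyc_per_um`` has shape (N, 2) in (ν_y, ν_x) order and is sorted
    center-outward, so index 0 is the on-axis (central) LED.
    """

    freqs_cyc_per_um: np.ndarray
    grid_spec: LedGridSpec | None = None
    led_index: np.ndarray | None = None  # (row, col) offsets per kept LED

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_cyc_per_um, dtype=float)
        if f.ndim != 2 or f.shape[1] != 2 or f.shape[0] < 1:
            raise ValueError("geometry needs an (N, 2) frequency array")
        object.__setattr__(self, "freqs_cyc_per_um", f)

    @property
    def n_leds(self) -> int:
        return self.freqs_cyc_per_um.shape[0]

    @property
    def magnitudes(self) -> np.ndarray:
        return np.hypot(*self.freqs_cyc_per_um.T[::-1])

    def illumination_na(self, wavelength_um: float) -> np.ndarray:
        return self.magnitudes * wavelength_um

    def max_frequency(self) -> float:
        return float(self.magnitudes.max())


def _grid_offsets(spec: LedGridSpec) -> np.ndarray:
    rr = np.arange(spec.rows) - (spec.rows - 1) / 2.0
    cc = np.arange(spec.cols) - (spec.cols - 1) / 2.0
    out = np.array([(r, c) for r in rr for c in cc])
    return out


def disk_radius_for_count(spec: LedGridSpec, target_n: int) -> float:
    """Disk radius (LED-index units) that keeps exactly ``target_n`` LEDs.

    The radii at which the kept-count changes are the distinct LED distances;
    returns the smallest distance whose cumulative count equals ``target_n``.
    Raises ``ValueError`` when no radius gives that count (lattice shells add
    several LEDs at once).
    """
    d = np.sort(np.hypot(*_grid_offsets(spec).T))
    counts = np.searchsorted(d, d, side="right")
    matches = np.nonzero(counts == target_n)[0]
    if matches.size == 0:
        raise ValueError(
            f"no disk truncation of a {spec.rows}x{spec.cols} grid keeps "
            f"exactly {target_n} LEDs")
    return float(d[matches[0]])


def build_led_geometry(spec: LedGridSpec, optics: OpticalSystem) -> LedGeometry:
    """Derive the ordered illumination-frequency list from an LED matrix.

    LEDs whose implied ``|ν|·λ >= 1`` (non-physical angle) are dropped with a
    warning.  The kept LEDs are ordered center-outward by ``|ν|`` so that the
    first entry is the on-axis LED used for bright-field initialization.
    """
    offsets = _grid_offsets(spec)
    if spec.keep_radius is not None:
        keep = np.hypot(*offsets.T) <= spec.keep_radius + 1e-9
        offsets = offsets[keep]
    if offsets.shape[0] == 0:
        raise ValueError("LED truncation removed every LED")

    y_mm = offsets[:, 0] * spec.pitch_mm
    x_mm = offsets[:, 1] * spec.pitch_mm
    hyp = np.sqrt(x_mm**2 + y_mm**2 + spec.height_mm**2)
    sin_y = y_mm / hyp
    sin_x = x_mm / hyp
    na_ill = np.hypot(sin_x, sin_y)

    physical = na_ill < 1.0  # sin of a real angle; defensive for odd configs
    if not np.all(physical):
        warnings.warn(
            f"dropping {np.count_nonzero(~physical)} LED(s) with non-physical "
            "illumination angle", stacklevel=2)
        offsets, sin_y, sin_x = offsets[physical], sin_y[physical], sin_x[physical]
    if offsets.shape[0] == 0:
        raise ValueError("no physically valid LEDs remain")

    freqs = np.stack([sin_y, sin_x], axis=1) / optics.wavelength_um
    mags = np.hypot(sin_x, sin_y)
    # stable center-outward order with a deterministic tie-break
    order = np.lexsort((offsets[:, 1], offsets[:, 0], np.round(mags, 12)))
    return LedGeometry(freqs_cyc_per_um=freqs[order], grid_spec=spec,
                       led_index=offsets[order])


@dataclass
class Pupil:
    """Complex pupil on the low-resolution spectral grid.

    ``values`` is identically zero outside ``support`` (circle of radius
    NA_MO/λ); :meth:`project` re-imposes that constraint after an update.
    """

    values: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.support = np.asarray(self.support, dtype=bool)
        if self.values.shape != self.support.shape:
            raise ValueError("pupil and support shapes differ")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def project(self) -> None:
        self.values[~self.support] = 0.0

    def copy(self) -> "Pupil":
        return Pupil(self.values.copy(), self.support.copy())


def _freq_grids(optics: OpticalSystem) -> tuple[np.ndarray, np.ndarray]:
    n = optics.grid_size
    idx = np.arange(n) - n // 2
    f = idx * optics.freq_step_cyc_per_um
    return np.meshgrid(f, f, indexing="ij")


def make_pupil(optics: OpticalSystem, phase: np.ndarray | None = None) -> Pupil:
    """Circular pupil of radius NA_MO/λ; unit amplitude, optional phase map."""
    fy, fx = _freq_grids(optics)
    support = fy**2 + fx**2 <= optics.cutoff_cyc_per_um**2
    values = support.astype(complex)
    if phase is not None:
        values = values * np.exp(1j * np.asarray(phase, dtype=float))
        values[~support] = 0.0
    return Pupil(values=values, support=support)


def defocus_phase(optics: OpticalSystem, defocus_um: float) -> np.ndarray:
    """Paraxial defocus aberration phase π·λ·z·|ν|² on the pupil grid (rad)."""
    fy, fx = _freq_grids(optics)
    return math.pi * optics.wavelength_um * defocus_um * (fy**2 + fx**2)
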