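"""Sequential Gerchberg–Saxton–Fienup retrieval of object and pupil.

Each LED visit simulates the pupil-plane field
``φ(ν) = O(ν − ν_n) P(ν)`` and the detector field ``Φ(r) = IFT(φ)``,
replaces the amplitude of Φ by the measured ``√I_n``, transforms back
(``φ' = FT(Φ')``) and applies gradient-descent style updates

    O(ν) ← O(ν) + G · (φ'(ν + ν_n) − φ(ν + ν_n)),
    P(ν) ← P(ν) + H · (φ'(ν) − φ(ν)),

with step maps

    G = |P| P* / ( max|P| · (|P|² + δ1) ),
    H = |O_w| O_w* / ( max|O| · (|O_w|² + δ2) ),

where ``O_w`` is the shifted object band seen through the window, the
maxima run over the full current estimates, and δ1, δ2 are small
regularizers.  One complete pass over all N LEDs is an outer loop; the loop
is repeated J times and the final spectrum is inverse transformed into the
high-resolution complex field.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from ._fft import fft2c, ifft2c, window_slices
from .optics import LedGeometry, OpticalSystem, Pupil, make_pupil
from .simulate import (HighResField, IntensityStack, hr_grid, shift_samples,
                       upsampling_factor)

__all__ = [
    "ReconConfig",
    "ReconState",
    "PhaseMap",
    "initialize_state",
    "update_once",
    "reconstruct",
    "extract_phase_map",
]


@dataclass(frozen=True)
class ReconConfig:
    """Retrieval settings.

    ``delta1``/``delta2`` regularize the object and pupil step maps (the
    update denominators); they are expressed relative to unit-normalized
    spectral amplitudes.  ``n_outer`` is the number J of complete passes.
    """

    n_outer: int = 20
    delta1: float = 1e-4
    delta2: float = 1e-4
    misfit_tol: float = 1e-6
    recover_pupil: bool = True

    def __post_init__(self) -> None:
        if self.n_outer < 1:
            raise ValueError("need at least one outer loop")
        if self.delta1 <= 0 or self.delta2 <= 0:
            raise ValueError("regularization constants must be positive")


@dataclass
class ReconState:
    """Mutable state of the retrieval: spectrum, pupil and misfit history."""

    spectrum: np.ndarray          # O^(j)(ν), high-res grid, DC centered
    pupil: Pupil                  # P^(j)(ν), low-res grid
    optics: OpticalSystem
    upsampling: int
    outer_done: int = 0
    misfit_history: list = dc_field(default_factory=list)

    @property
    def hr_shape(self) -> tuple[int, int]:
        return self.spectrum.shape

    @property
    def lr_shape(self) -> tuple[int, int]:
        return self.pupil.values.shape


def initialize_state(stack: IntensityStack, geom: LedGeometry,
                     optics: OpticalSystem,
                     config: ReconConfig) -> ReconState:
    """Bright-field initialization of object spectrum and pupil.

    The object guess is the Fourier-upsampled square root of the central
    bright-field image with zero phase; the pupil starts as the unit-amplitude
    support circle with constant (zero) phase.
    """
    na_ill = geom.illumination_na(optics.wavelength_um)
    if na_ill[0] >= optics.na_mo:
        raise ValueError("no bright-field (on-axis) LED available for "
                         "initialization")
    u = upsampling_factor(optics, geom)
    n_lr = optics.grid_size
    n_hr = n_lr * u
    amp = np.sqrt(stack.images[0])
    lr_spec = fft2c(amp)
    spectrum = np.zeros((n_hr, n_hr), dtype=complex)
    spectrum[window_slices((n_hr, n_hr), (n_lr, n_lr), (0, 0))] = lr_spec
    pupil = make_pupil(optics)
    return ReconState(spectrum=spectrum, pupil=pupil, optics=optics,
                      upsampling=u)


def _step_maps(w: np.ndarray, P: np.ndarray, spectrum: np.ndarray,
               config: ReconConfig) -> tuple[np.ndarray, np.ndarray]:
    absP = np.abs(P)
    absW = np.abs(w)
    G = absP * np.conj(P) / (absP.max() * (absP**2 + config.delta1))
    H = absW * np.conj(w) / (np.abs(spectrum).max() * (absW**2 + config.delta2))
    return G, H


def update_once(state: ReconState, image: np.ndarray,
                shift: tuple[int, int], config: ReconConfig,
                led_index: int | None = None) -> float:
    """One Eq. 1–4 update of the state for a single LED measurement.

    ``shift`` is the integer spectral-sample shift of the LED's carrier
    frequency.  Mutates ``state`` in place and returns this LED's amplitude
    misfit ``‖√I − |Φ|‖²`` (for the outer-loop history).
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("intensity image must be non-negative")
    sy, sx = int(shift[0]), int(shift[1])
    try:
        win = window_slices(state.hr_shape, state.lr_shape, (-sy, -sx))
    except ValueError as exc:
        raise ValueError(f"LED {led_index}: spectral shift {shift} out of "
                         "range") from exc
    P = state.pupil.values
    w = state.spectrum[win]

    phi = w * P
    Phi = ifft2c(phi)
    sqrtI = np.sqrt(image)
    absPhi = np.abs(Phi)
    # amplitude replacement; where |Φ| = 0 keep √I at zero phase
    unit = np.ones_like(Phi)
    np.divide(Phi, absPhi, out=unit, where=absPhi > 0)
    Phi_new = sqrtI * unit
    phi_new = fft2c(Phi_new)

    diff = phi_new - phi
    G, H = _step_maps(w, P, state.spectrum, config)
    state.spectrum[win] = w + G * diff
    if config.recover_pupil:
        state.pupil.values = P + H * diff
        state.pupil.project()

    if not np.all(np.isfinite(state.spectrum[win])):
        raise FloatingPointError(f"non-finite object update at LED {led_index}")
    return float(np.sum((sqrtI - absPhi) ** 2))


def reconstruct(stack: IntensityStack, geom: LedGeometry,
                optics: OpticalSystem, config: ReconConfig = ReconConfig(),
                ) -> tuple[HighResField, Pupil, list[float]]:
    """Run J outer loops over all LEDs and return field, pupil and misfits.

    The relative amplitude misfit ``Σ_n‖√I_n − |Φ_n|‖² / Σ_n‖√I_n‖²`` is
    recorded once per outer loop (evaluated as each LED is visited).  Raises
    ``RuntimeError`` on divergence (misfit above 10× the initial value).
    """
    state = initialize_state(stack, geom, optics, config)
    shifts = shift_samples(geom, optics)
    norm = float(np.sum(stack.images))  # Σ‖√I‖² = Σ I
    if norm == 0:
        raise ValueError("stack carries no energy")
    for j in range(config.n_outer):
        total = 0.0
        for i in range(geom.n_leds):
            total += update_once(state, stack.images[i], shifts[i], config,
                                 led_index=i)
        misfit = total / norm
        state.misfit_history.append(misfit)
        state.outer_done = j + 1
        if misfit > 10.0 * state.misfit_history[0] + 1e-30:
            raise RuntimeError(
                f"retrieval diverged at outer loop {j + 1}: "
                f"misfit history {state.misfit_history}")
        if misfit < config.misfit_tol:
            break
    _, hr_pixel = hr_grid(optics, geom)
    fieldobj = HighResField(data=ifft2c(state.spectrum), pixel_um=hr_pixel,
                            provenance="reconstructed",
                            meta={"outer_loops": state.outer_done,
                                  "misfit_history": list(state.misfit_history)})
    return fieldobj, state.pupil, list(state.misfit_history)


# ---------------------------------------------------------------------------
# phase map extraction


@dataclass
class PhaseMap:
    """Real-valued phase image (rad) with its sample-plane pixel pitch."""

    values: np.ndarray
    pixel_um: float
    provenance: str = "reconstructed"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phase map must be finite")
        if self.pixel_um <= 0:
            raise ValueError("pixel pitch must be positive")


def _poly2_background(phase: np.ndarray) -> np.ndarray:
    """Robust second-order polynomial background via sigma clipping."""
    ny, nx = phase.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    y = (yy / max(ny - 1, 1) - 0.5).ravel()
    x = (xx / max(nx - 1, 1) - 0.5).ravel()
    A = np.stack([np.ones_like(x), x, y, x * x, x * y, y * y], axis=1)
    z = phase.ravel()
    keep = np.ones(z.size, dtype=bool)
    coef = np.zeros(6)
    for _ in range(3):
        coef, *_ = np.linalg.lstsq(A[keep], z[keep], rcond=None)
        resid = z - A @ coef
        sigma = np.std(resid[keep])
        if sigma == 0:
            break
        keep = np.abs(resid) < 2.5 * sigma
        if keep.sum() < 8:
            break
    return (A @ coef).reshape(phase.shape)


def extract_phase_map(fieldobj: HighResField,
                      flatten: bool = False) -> PhaseMap:
    """Phase-contrast map arg o(r) ∈ (−π, π], optionally background-flattened.

    Flattening subtracts a sigma-clipped second-order polynomial fit of the
    background (tilt/curvature of the illumination), leaving object phase
    referenced to a zero background.  No unwrapping is performed; a warning
    is raised when ≥1% of pixels sit within 1% of ±π (possible wrap-around).
    """
    phase = np.angle(fieldobj.data)
    near_wrap = np.mean(np.abs(phase) > 0.99 * np.pi)
    if near_wrap >= 0.01:
        import warnings
        warnings.warn(f"{near_wrap:.1%} of pixels near ±π: phase may wrap",
                      stacklevel=2)
    if flatten:
        phase = phase - _poly2_background(phase)
    return PhaseMap(values=phase, pixel_um=fieldobj.pixel_um,
                    provenance=fieldobj.provenance)
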