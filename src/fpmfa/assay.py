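"""Dose calibration curves and the two-step Cu dose-interval classifier.

Calibration fits the multi-scale lacunarity (MSL) of control/exposed fields
against the Cu dose with a three-parameter exponential, y = a·exp(b·x) + c
(b > 0 so the curve grows with dose), and the range GLCM entropy Δs against
the low-dose range with a cubic polynomial.  A measured descriptor is then
inverted through its calibration curve to a dose estimate and binned:

* Step 1 (MSL, 72 h exposure): four intervals
  [0, 17.5), [17.5, 22.5), [22.5, 30), [30, ∞) µM.
* Step 2 (entropy, only when step 1 lands in the lowest interval): four
  sub-intervals [0, 2.5), [2.5, 7.5), [7.5, 12.5), [12.5, 17.5) µM,

so each water sample receives one of seven dose-interval labels.  The 48 h
exposure (T2) variant resolves only three intervals
([0, 30), [30, 42.5), [42.5, ∞)) because its calibration curve is flatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "CalibrationModel",
    "DecisionTable",
    "DoseCall",
    "T3_STEP1_BOUNDS",
    "T2_STEP1_BOUNDS",
    "STEP2_BOUNDS",
    "fit_exponential",
    "fit_cubic",
    "invert_calibration",
    "build_decision_table",
    "classify_dose",
]

T3_STEP1_BOUNDS = (17.5, 22.5, 30.0)
T2_STEP1_BOUNDS = (30.0, 42.5)
STEP2_BOUNDS = (2.5, 7.5, 12.5)


@dataclass
class CalibrationModel:
    """A fitted dose–descriptor curve with its validity domain.

    ``family`` is ``"exponential"`` (coefficients a, b, c of a·exp(b·x)+c)
    or ``"cubic"`` (polynomial coefficients, highest power first).
    ``residual_scale`` is the RMS fit residual in descriptor units.
    """

    family: str
    coefficients: np.ndarray
    dose_domain: tuple[float, float]
    residual_scale: float
    exposure: str = "T3"
    monotonic: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        lo, hi = self.dose_domain
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
            raise ValueError("dose domain must be a finite interval")

    def predict(self, dose: float | np.ndarray) -> np.ndarray:
        x = np.asarray(dose, dtype=float)
        if self.family == "exponential":
            a, b, c = self.coefficients
            return a * np.exp(b * x) + c
        if self.family == "cubic":
            return np.polyval(self.coefficients, x)
        raise ValueError(f"unknown model family {self.family!r}")

    def to_dict(self) -> dict:
        return {"family": self.family,
                "coefficients": self.coefficients.tolist(),
                "dose_domain": list(self.dose_domain),
                "residual_scale": self.residual_scale,
                "exposure": self.exposure,
                "monotonic": self.monotonic}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(family=d["family"],
                   coefficients=np.asarray(d["coefficients"]),
                   dose_domain=tuple(d["dose_domain"]),
                   residual_scale=float(d["residual_scale"]),
                   exposure=d.get("exposure", "T3"),
                   monotonic=bool(d.get("monotonic", True)))


def _check_calibration_input(doses, values, min_points):
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    if doses.shape != values.shape or doses.ndim != 1:
        raise ValueError("doses and values must be matching 1-D arrays")
    if doses.size < min_points:
        raise ValueError(f"need at least {min_points} calibration points")
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if np.unique(doses).size != doses.size:
        raise ValueError("doses must be distinct")
    order = np.argsort(doses)
    return doses[order], values[order]


def fit_exponential(doses, values, exposure: str = "T3") -> CalibrationModel:
    """Least-squares fit of y = a·exp(b·x) + c with b constrained positive.

    Emits a warning when the data are not monotone beyond the fit's residual
    scale (the curve itself is monotone by construction for a, b > 0).
    """
    x, y = _check_calibration_input(doses, values, 4)
    span = max(np.ptp(y), 1e-12)
    xspan = max(x[-1] - x[0], 1e-12)
    b0 = 1.0 / xspan
    a0 = max(span, 1e-9) / max(np.expm1(b0 * xspan), 1e-9)
    p0 = (a0, b0, y[0] - a0)
    try:
        coef, _ = curve_fit(lambda t, a, b, c: a * np.exp(b * t) + c, x, y,
                            p0=p0, maxfev=20000,
                            bounds=([0.0, 1e-9, -np.inf],
                                    [np.inf, 10.0 / max(xspan, 1e-9), np.inf]))
    except RuntimeError as exc:
        raise RuntimeError(f"exponential calibration failed: {exc}") from exc
    resid = y - (coef[0] * np.exp(coef[1] * x) + coef[2])
    scale = float(np.sqrt(np.mean(resid**2)))
    if np.any(np.diff(y) < -max(2 * scale, 1e-12)):
        warnings.warn("calibration data are not monotone within the fit "
                      "residual scale", stacklevel=2)
    return CalibrationModel(family="exponential", coefficients=coef,
                            dose_domain=(float(x[0]), float(x[-1])),
                            residual_scale=scale, exposure=exposure)


def fit_cubic(doses, values, exposure: str = "T3") -> CalibrationModel:
    """Least-squares cubic for the low-dose entropy calibration."""
    x, y = _check_calibration_input(doses, values, 5)
    coef = np.polyfit(x, y, 3)
    resid = y - np.polyval(coef, x)
    scale = float(np.sqrt(np.mean(resid**2)))
    # monotonicity on the fitted domain via the derivative sign
    deriv = np.polyval(np.polyder(coef), np.linspace(x[0], x[-1], 512))
    monotonic = bool(np.all(deriv >= -1e-12 * max(1.0, np.abs(deriv).max())))
    if not monotonic:
        warnings.warn("cubic calibration is not monotone on its domain; "
                      "inversion will use its monotone envelope",
                      stacklevel=2)
    return CalibrationModel(family="cubic", coefficients=coef,
                            dose_domain=(float(x[0]), float(x[-1])),
                            residual_scale=scale, exposure=exposure,
                            monotonic=monotonic)


def invert_calibration(model: CalibrationModel,
                       value: float) -> tuple[float, bool]:
    """Dose estimate (µM) for a measured descriptor value.

    Returns ``(dose, out_of_range)``.  The exponential family inverts in
    closed form, x = ln((y − c)/a)/b; the cubic by root bracketing on its
    monotone restriction.  Values outside the curve's range over the dose
    domain clamp to the nearest endpoint with the flag set.
    """
    if not np.isfinite(value):
        raise ValueError("measured value must be finite")
    lo, hi = model.dose_domain
    if model.family == "exponential":
        a, b, c = model.coefficients
        if value <= c or a <= 0:
            return lo, True
        x = np.log((value - c) / a) / b
        if x < lo:
            return lo, True
        if x > hi:
            return hi, True
        return float(x), False
    if model.family == "cubic":
        if model.monotonic:
            f = lambda t: float(np.polyval(model.coefficients, t)) - value
            flo, fhi = f(lo), f(hi)
            if flo >= 0:
                return lo, flo > 0
            if fhi <= 0:
                return hi, fhi < 0
            return float(brentq(f, lo, hi, xtol=1e-10)), False
        # monotone envelope: running maximum over a dense grid
        grid = np.linspace(lo, hi, 4097)
        env = np.maximum.accumulate(np.polyval(model.coefficients, grid))
        if value <= env[0]:
            return lo, value < env[0]
        if value >= env[-1]:
            return hi, value > env[-1]
        return float(np.interp(value, env, grid)), False
    raise ValueError(f"unknown model family {model.family!r}")


# ---------------------------------------------------------------------------
# decision table


def _format_interval(lo: float, hi: float) -> str:
    top = "∞" if np.isinf(hi) else f"{hi:g}"
    return f"[{lo:g}, {top}) µM"


@dataclass(frozen=True)
class DecisionTable:
    """Two-step dose-interval partition.

    Step-1 boundaries split [0, ∞) for the MSL stage; step-2 boundaries
    subdivide the lowest step-1 interval for the entropy stage, which runs
    only when step 1 lands there.
    """

    step1_bounds: tuple[float, ...]
    step2_bounds: tuple[float, ...]

    def __post_init__(self) -> None:
        s1 = tuple(float(b) for b in self.step1_bounds)
        s2 = tuple(float(b) for b in self.step2_bounds)
        if len(s1) < 1:
            raise ValueError("step 1 needs at least one boundary")
        for bounds, name in ((s1, "step-1"), (s2, "step-2")):
            if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
                raise ValueError(f"{name} boundaries must be strictly "
                                 "increasing")
        if any(b <= 0 for b in s1) or any(b <= 0 for b in s2):
            raise ValueError("boundaries must be positive doses")
        if s2 and s2[-1] >= s1[0]:
            raise ValueError("step-2 boundaries must partition the lowest "
                             f"step-1 interval [0, {s1[0]})")
        object.__setattr__(self, "step1_bounds", s1)
        object.__setattr__(self, "step2_bounds", s2)

    @property
    def step1_edges(self) -> list[tuple[float, float]]:
        e = [0.0, *self.step1_bounds, np.inf]
        return list(zip(e[:-1], e[1:]))

    @property
    def step2_edges(self) -> list[tuple[float, float]]:
        e = [0.0, *self.step2_bounds, self.step1_bounds[0]]
        return list(zip(e[:-1], e[1:]))

    @property
    def step1_labels(self) -> list[str]:
        return [_format_interval(lo, hi) for lo, hi in self.step1_edges]

    @property
    def step2_labels(self) -> list[str]:
        return [_format_interval(lo, hi) for lo, hi in self.step2_edges]

    @property
    def labels(self) -> list[str]:
        """Final label set: step-2 sub-intervals plus upper step-1 intervals."""
        if not self.step2_bounds:
            return self.step1_labels
        return self.step2_labels + self.step1_labels[1:]

    def bin_step1(self, dose: float) -> int:
        return int(np.searchsorted(self.step1_bounds, dose, side="right"))

    def bin_step2(self, dose: float) -> int:
        dose = min(dose, np.nextafter(self.step1_bounds[0], 0.0))
        return int(np.searchsorted(self.step2_bounds, dose, side="right"))

    def label_for_dose(self, dose: float) -> str:
        """Final label containing a known true dose (for validation)."""
        if dose < 0:
            raise ValueError("dose must be non-negative")
        i = self.bin_step1(dose)
        if i == 0 and self.step2_bounds:
            return self.step2_labels[self.bin_step2(dose)]
        return self.step1_labels[i]


def build_decision_table(step1_bounds=T3_STEP1_BOUNDS,
                         step2_bounds=STEP2_BOUNDS) -> DecisionTable:
    """Validated decision table; defaults are the printed dose boundaries."""
    return DecisionTable(step1_bounds=tuple(step1_bounds),
                         step2_bounds=tuple(step2_bounds))


@dataclass
class DoseCall:
    """Outcome of the two-step classification of one measured field."""

    msl: float
    delta_s: float | None
    step1_dose_um: float
    step1_out_of_range: bool
    label: str
    step2_dose_um: float | None = None
    step2_out_of_range: bool | None = None
    steps_run: tuple[str, ...] = ("msl",)

    def to_dict(self) -> dict:
        return {"msl": self.msl, "delta_s": self.delta_s,
                "step1_dose_um": self.step1_dose_um,
                "step1_out_of_range": self.step1_out_of_range,
                "step2_dose_um": self.step2_dose_um,
                "step2_out_of_range": self.step2_out_of_range,
                "label": self.label, "steps_run": list(self.steps_run)}


def classify_dose(msl: float, delta_s: float | None,
                  msl_model: CalibrationModel,
                  entropy_model: CalibrationModel | None,
                  table: DecisionTable) -> DoseCall:
    """Map a measured (MSL, Δs) pair to one of the table's dose intervals.

    Step 1 inverts the MSL calibration and bins the dose estimate.  When the
    estimate falls in the lowest interval and the table defines sub-intervals,
    step 2 inverts the entropy calibration; Δs (and its model) are then
    required.
    """
    d1, oor1 = invert_calibration(msl_model, msl)
    i1 = table.bin_step1(d1)
    if i1 > 0 or not table.step2_bounds:
        return DoseCall(msl=msl, delta_s=delta_s, step1_dose_um=d1,
                        step1_out_of_range=oor1,
                        label=table.step1_labels[i1], steps_run=("msl",))
    if delta_s is None or entropy_model is None:
        raise ValueError("step-1 estimate is in the lowest interval: the "
                         "entropy measurement Δs and its calibration are "
                         "required for step 2")
    d2, oor2 = invert_calibration(entropy_model, delta_s)
    return DoseCall(msl=msl, delta_s=delta_s, step1_dose_um=d1,
                    step1_out_of_range=oor1, step2_dose_um=d2,
                    step2_out_of_range=oor2,
                    label=table.step2_labels[table.bin_step2(d2)],
                    steps_run=("msl", "entropy"))
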