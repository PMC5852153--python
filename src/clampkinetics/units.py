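"""Unit conversions, body-size formulas, and the two model forcing functions.

The model consumes two exogenous inputs: the plasma-glucose step function
``G(t)`` built from 5-min-average clamp readings, and the serum-equivalent
insulin infusion ``f(t)`` fitted to the prime-then-constant infusion profile
of the hyperinsulinemic-euglycemic clamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class UnitConstants:
    """Physical constants used in clinical-unit conversions.

    insulin_conversion : pM per (uU/mL), from 6.00 nmol/U.
    glucose_mw, cpeptide_mw : molecular weights in g/mol.
    blood_volume_* : blood volume in mL per kg body weight.
    """

    insulin_conversion: float = 6.00
    glucose_mw: float = 180.16
    cpeptide_mw: float = 3020.3
    blood_volume_male: float = 75.0
    blood_volume_female: float = 65.0

    def __post_init__(self) -> None:
        for name in (
            "insulin_conversion",
            "glucose_mw",
            "cpeptide_mw",
            "blood_volume_male",
            "blood_volume_female",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def blood_volume(self, sex: str) -> float:
        if sex == "male":
            return self.blood_volume_male
        if sex == "female":
            return self.blood_volume_female
        raise ValueError(f"unknown sex {sex!r}; expected 'male' or 'female'")


CONSTANTS = UnitConstants()


def convert_iir_to_cIIR(iir: float, sex: str, constants: UnitConstants = CONSTANTS) -> float:
    """Convert an insulin infusion rate (mU/kg/min) to its serum-concentration
    equivalent in pM/min: IIR * 6.00 pmol/mU / (BV * 1e-3 L/kg), with the
    blood volume BV in mL/kg chosen by sex.

    For the standard steady infusion of 1.46 mU/kg/min in a man this gives
    116.8 pM/min, which with peripheral clearances around 0.2/min sustains the
    several-hundred-pM hyperinsulinemic plateaus seen clinically.
    """
    if iir < 0:
        raise ValueError(f"insulin infusion rate must be nonnegative, got {iir}")
    bv = constants.blood_volume(sex)
    return iir * constants.insulin_conversion / (bv * 1e-3)


_QUANTITIES = ("glucose_mgdl_to_mM", "insulin_uUml_to_pM", "cpeptide_ngml_to_pM")


def convert_units(
    value: float,
    quantity: str,
    inverse: bool = False,
    constants: UnitConstants = CONSTANTS,
) -> float:
    """Clinical-unit conversions.

    glucose_mgdl_to_mM   : mg/dL -> mM, factor 10/180.16
    insulin_uUml_to_pM   : uU/mL -> pM, factor 6.00
    cpeptide_ngml_to_pM  : ng/mL -> pM, factor 1e6/3020.3

    ``inverse=True`` applies the reverse conversion.
    """
    if np.any(np.asarray(value) < 0):
        raise ValueError("concentrations must be nonnegative")
    if quantity == "glucose_mgdl_to_mM":
        factor = 10.0 / constants.glucose_mw
    elif quantity == "insulin_uUml_to_pM":
        factor = constants.insulin_conversion
    elif quantity == "cpeptide_ngml_to_pM":
        factor = 1e6 / constants.cpeptide_mw
    else:
        raise ValueError(f"unknown quantity {quantity!r}; expected one of {_QUANTITIES}")
    return value / factor if inverse else value * factor


def body_surface_area(weight: float, height: float) -> float:
    """Mosteller body surface area: sqrt(weight[kg]) * sqrt(height[cm]) / 60, in m^2."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be strictly positive")
    return np.sqrt(weight) * np.sqrt(height) / 60.0


@dataclass(frozen=True)
class GlucoseInput:
    """Right-continuous step function for plasma glucose (mM).

    ``pre_window_value`` holds before the first breakpoint; at a breakpoint the
    new value applies (right-continuity).
    """

    breakpoints: np.ndarray
    values: np.ndarray
    pre_window_value: float

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if bp.shape != vals.shape:
            raise ValueError("breakpoints and values must have equal length")
        if bp.size and np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(vals < 0) or self.pre_window_value < 0:
            raise ValueError("glucose values must be nonnegative")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.maximum(idx, 0)], self.pre_window_value)
        return out if out.ndim else float(out)

    @property
    def max_value(self) -> float:
        return float(max(self.values.max(initial=0.0), self.pre_window_value))


def build_glucose_input(sample_times, avg_values, fasting_glucose: float) -> GlucoseInput:
    """Stepwise interpolation of 5-min-average plasma glucose.

    Each sampling time is reduced by 2 min (the averages are centered back into
    their window); before the first shifted breakpoint the subject is assumed at
    fasting steady state.
    """
    times = np.asarray(sample_times, dtype=float)
    vals = np.asarray(avg_values, dtype=float)
    if times.shape != vals.shape:
        raise ValueError(
            f"sample_times (n={times.size}) and avg_values (n={vals.size}) differ in length"
        )
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("sample times must be strictly increasing")
    return GlucoseInput(breakpoints=times - 2.0, values=vals, pre_window_value=fasting_glucose)


@dataclass(frozen=True)
class InfusionFunction:
    """Serum-equivalent insulin infusion f(t) = ii1*exp(ii2*(t-onset)) + ii3
    for t > onset_time, zero otherwise (pM/min)."""

    ii1: float
    ii2: float
    ii3: float
    onset_time: float = 100.0
    residual_norm: float = 0.0
    converged: bool = True

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        dt = t - self.onset_time
        active = dt > 0
        out = np.where(
            active, self.ii1 * np.exp(self.ii2 * np.where(active, dt, 0.0)) + self.ii3, 0.0
        )
        return out if out.ndim else float(out)

    def integral(self, a: float, b: float) -> float:
        """Exact integral of f over [a, b]."""
        if b <= a:
            return 0.0
        a = max(a, self.onset_time)
        if b <= a:
            return 0.0
        ta, tb = a - self.onset_time, b - self.onset_time
        if self.ii2 == 0.0:
            expo = self.ii1 * (tb - ta)
        else:
            expo = self.ii1 / self.ii2 * (np.exp(self.ii2 * tb) - np.exp(self.ii2 * ta))
        return float(expo + self.ii3 * (tb - ta))


ZERO_INFUSION = InfusionFunction(0.0, 0.0, 0.0, onset_time=np.inf)


def fit_infusion_function(times, ciir, onset_time: float = 100.0) -> InfusionFunction:
    """Least-squares fit of ii1*exp(ii2*(t-onset)) + ii3 to post-onset cIIR data.

    Bounded trust-region least squares from three starts spread over decaying
    time constants, to avoid the flat (constant-only) local minimum.
    """
    times = np.asarray(times, dtype=float)
    ciir = np.asarray(ciir, dtype=float)
    mask = times > onset_time
    t = times[mask] - onset_time
    y = ciir[mask]
    if t.size < 3:
        raise ValueError(f"need at least 3 points after t={onset_time}, got {t.size}")

    def resid(p):
        return p[0] * np.exp(p[1] * t) + p[2] - y

    span = max(float(y.max() - y.min()), 1e-12)
    lo = [0.0, -5.0, 0.0]
    hi = [np.inf, 0.0, np.inf]
    best = None
    ok = False
    for ii2_0 in (-0.5, -0.1, -0.02):
        x0 = [max(y[0] - y[-1], span, 1e-9), ii2_0, max(float(y[-1]), 0.0)]
        sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
            ok = sol.success
    rnorm = float(np.sqrt(2.0 * best.cost))
    return InfusionFunction(
        ii1=float(best.x[0]),
        ii2=float(best.x[1]),
        ii3=float(best.x[2]),
        onset_time=onset_time,
        residual_norm=rnorm,
        converged=bool(ok),
    )
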