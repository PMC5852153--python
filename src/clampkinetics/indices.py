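"""Temporal-pattern indices of the insulin curve and clinical clamp indices.

``ipeak`` is the incremental first-phase peak, I(t_local_max) - I(0), and
``iTPI`` the incremental transient peak index,
(I(t_local_max) - I(t_local_min)) / ipeak: 1 means a fully transient response
(returns to baseline before the second phase), 0 a fully sustained one. Both
are evaluated on whatever time grid the series provides — the simulation grid
for model trajectories, the 9 clinical sampling times for measured series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import body_surface_area


@dataclass(frozen=True)
class PeakIndices:
    ipeak: float
    iTPI: float
    t_local_max: float
    t_local_min: float
    defined: bool
    reason: str = ""


def _first_strict_decrease(values: np.ndarray) -> int | None:
    """Index k of the first value with values[k] > values[k+1]; plateaus do
    not terminate an increase."""
    drops = np.nonzero(values[:-1] > values[1:])[0]
    return int(drops[0]) if drops.size else None


def peak_indices(times, I_series, I0: float | None = None) -> PeakIndices:
    """Locate the first local maximum and subsequent local minimum of I.

    Undefined (with a reason code) when the series rises monotonically or when
    no local minimum occurs before the series ends.
    """
    t = np.asarray(times, dtype=float)
    I = np.asarray(I_series, dtype=float)
    if t.size != I.size:
        raise ValueError("times and series must have equal length")
    if t.size < 3:
        raise ValueError("need at least 3 points to locate a peak")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if I0 is None:
        I0 = float(I[0])

    k = _first_strict_decrease(I)
    if k is None:
        return PeakIndices(np.nan, np.nan, np.nan, np.nan, False, "no_local_max")
    ipeak = float(I[k] - I0)
    if ipeak <= 0:
        return PeakIndices(np.nan, np.nan, float(t[k]), np.nan, False, "nonpositive_peak")
    rest = I[k:]
    j = _first_strict_decrease(-rest)
    if j is None:
        return PeakIndices(ipeak, np.nan, float(t[k]), np.nan, False, "no_local_min")
    j += k
    itpi = float((I[k] - I[j]) / ipeak)
    return PeakIndices(ipeak, itpi, float(t[k]), float(t[j]), True)


def auc_iri10(times, iri, fasting_iri: float) -> float:
    """Incremental trapezoidal area of IRI above fasting over [0, 10] min
    (uU/mL * min). Requires samples at t=0 and t=10."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(iri, dtype=float)
    mask = t <= 10.0 + 1e-9
    t, y = t[mask], y[mask]
    if t.size < 2 or not np.isclose(t[0], 0.0) or not np.isclose(t[-1], 10.0):
        raise ValueError("AUC_IRI10 requires samples at t=0 and t=10 min")
    return float(np.trapezoid(y - fasting_iri, t))


def isi(mean_gir_final30: float, end_glucose: float, end_insulin: float) -> float:
    """Insulin sensitivity index: GIR / (G_end * I_end) * 100, with GIR in
    mg/kg/min, glucose in mg/dL and insulin in uU/mL."""
    if end_glucose <= 0 or end_insulin <= 0:
        raise ValueError("end-of-clamp glucose and insulin must be positive")
    return float(mean_gir_final30 / (end_glucose * end_insulin) * 100.0)


def mcr(weight: float, height: float, end_iri: float, fasting_iri: float) -> float:
    """Metabolic clearance rate of insulin at the infusion steady state:
    1.46 mU/kg/min * weight * BSA / (end IRI - fasting IRI)."""
    inc = end_iri - fasting_iri
    if inc <= 0:
        raise ValueError("end IRI must exceed fasting IRI")
    return float(1.46 * weight * body_surface_area(weight, height) / inc)


def clamp_di(auc_iri10_value: float, isi_value: float) -> float:
    """Clamp disposition index: product of AUC_IRI10 and ISI."""
    return float(auc_iri10_value * isi_value)
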