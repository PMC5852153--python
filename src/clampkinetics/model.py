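"""Serum insulin / C-peptide kinetics under clamp forcing.

Four states driven by the plasma-glucose step input G(t) and the insulin
infusion f(t):

    dY/dt  = alpha*(beta*(G - h) - Y)      if G > h, else -alpha*Y
    dX/dt  = Y - m*X                       if G > h, else Y
    dI/dt  = k_ratio*m*X - k_Iout*(I - I_b) + f(t)   (secretion term only if G > h)
    dCP/dt = m*X - k_CPout*(CP - CP_b)               (secretion term only if G > h)

Y is the glucose-driven provision rate feeding the stored pool X; m*X is the
equimolar secretion flux of insulin and C-peptide. Only the fraction k_ratio of
secreted insulin survives first-pass hepatic extraction, so (1 - k_ratio) is
the hepatic insulin clearance; k_Iout and k_CPout are the peripheral clearance
rate constants. I_b and CP_b are measured fasting values and double as initial
conditions, with Y(0) = 0 and X(0) = X_b.

G is piecewise constant, so the right-hand side is piecewise linear and the
G > h switch can only toggle at glucose breakpoints; ``simulate`` integrates
segment-by-segment with the switch frozen per segment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .units import GlucoseInput, InfusionFunction, ZERO_INFUSION

#: Order of the estimated parameters throughout the package.
PARAM_NAMES = ("alpha", "beta", "h", "m", "X_b", "k_ratio", "k_Iout", "k_CPout")


@dataclass(frozen=True)
class ModelParameters:
    """Model parameter vector plus measured basal values.

    alpha   : 1/min, relaxation rate of the provision rate Y
    beta    : provision gain per mM of glucose above threshold
    h       : mM, glucose threshold for secretion (corresponds to FPG)
    m       : 1/min, secretion rate of the stored pool
    X_b     : pM-equivalent, initial stored pool
    k_ratio : post-hepatic fraction of secreted insulin, in (0, 1] at estimation
    k_Iout  : 1/min, peripheral insulin clearance
    k_CPout : 1/min, peripheral C-peptide clearance
    I_b, CP_b : pM, fasting serum insulin and C-peptide (measured, not fitted)
    """

    alpha: float
    beta: float
    h: float
    m: float
    X_b: float
    k_ratio: float
    k_Iout: float
    k_CPout: float
    I_b: float
    CP_b: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta, I_b: float, CP_b: float) -> "ModelParameters":
        theta = np.asarray(theta, dtype=float)
        return cls(*theta, I_b=I_b, CP_b=CP_b)

    def replace(self, **kw) -> "ModelParameters":
        return dataclasses.replace(self, **kw)

    def scaled(self, name: str, factor: float) -> "ModelParameters":
        return self.replace(**{name: getattr(self, name) * factor})


@dataclass
class Trajectory:
    """Simulated time courses on a dense grid.

    ``integrals`` carries cumulative quadratures accumulated as extra ODE
    states: secretion ``int_v`` = cumulative m*X*(G>h), ``int_I_dev`` =
    cumulative (I - I_b), ``int_CP_dev`` = cumulative (CP - CP_b), and
    ``int_f`` = cumulative infused insulin.
    """

    times: np.ndarray
    Y: np.ndarray
    X: np.ndarray
    I: np.ndarray
    CP: np.ndarray
    integrals: dict
    params: ModelParameters

    def sample(self, sample_times) -> tuple[np.ndarray, np.ndarray]:
        """Exact grid evaluations of (I, CP) at ``sample_times``.

        Raises if a requested time is not on the simulation grid.
        """
        st = np.asarray(sample_times, dtype=float)
        idx = np.searchsorted(self.times, st)
        idx = np.clip(idx, 0, self.times.size - 1)
        if not np.allclose(self.times[idx], st, rtol=0, atol=1e-9):
            missing = st[~np.isclose(self.times[idx], st, rtol=0, atol=1e-9)]
            raise ValueError(f"sampling times {missing} not on the simulation grid")
        return self.I[idx], self.CP[idx]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_min": self.times, "Y": self.Y, "X": self.X, "I_pM": self.I, "CP_pM": self.CP}
        )


def derivatives(
    state,
    t: float,
    params: ModelParameters,
    G: GlucoseInput,
    f: InfusionFunction = ZERO_INFUSION,
) -> np.ndarray:
    """Right-hand side (dY, dX, dI, dCP) at time t. Ties G == h take the
    sub-threshold branch."""
    Y, X, I, CP = np.asarray(state, dtype=float)[:4]
    g = float(G(t))
    p = params
    if g > p.h:
        v = p.m * X
        dY = p.alpha * (p.beta * (g - p.h) - Y)
    else:
        v = 0.0
        dY = -p.alpha * Y
    dX = Y - v
    dI = p.k_ratio * v - p.k_Iout * (I - p.I_b) + float(f(t))
    dCP = v - p.k_CPout * (CP - p.CP_b)
    return np.array([dY, dX, dI, dCP])


def _segment_edges(G: GlucoseInput, f: InfusionFunction, t_end: float) -> np.ndarray:
    edges = {0.0, float(t_end)}
    for b in G.breakpoints:
        if 0.0 < b < t_end:
            edges.add(float(b))
    if np.isfinite(f.onset_time) and 0.0 < f.onset_time < t_end:
        edges.add(float(f.onset_time))
    return np.array(sorted(edges))


def simulate(
    params: ModelParameters,
    G: GlucoseInput,
    f: InfusionFunction = ZERO_INFUSION,
    t_end: float = 220.0,
    grid_step: float = 1.0,
    sample_times=None,
    rtol: float = 1e-10,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the model over [0, t_end], restarting at every glucose
    breakpoint and at the infusion onset so each segment has a smooth RHS.

    The returned grid is ``arange(0, t_end, grid_step)`` plus t_end, the
    segment edges and any requested ``sample_times`` (so sampled values are
    exact grid evaluations, not interpolations).
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    p = params
    edges = _segment_edges(G, f, t_end)
    grid = np.arange(0.0, t_end + grid_step * 0.5, grid_step)
    pts = {round(float(t), 9) for t in grid if t <= t_end}
    pts.update(round(float(t), 9) for t in edges)
    if sample_times is not None:
        for t in np.asarray(sample_times, dtype=float):
            if t < 0 or t > t_end:
                raise ValueError(f"sample time {t} outside [0, {t_end}]")
            pts.add(round(float(t), 9))
    all_times = np.array(sorted(pts))

    y0 = np.array([0.0, p.X_b, p.I_b, p.CP_b, 0.0, 0.0, 0.0, 0.0])
    out = [y0]
    times_out = [0.0]
    for a, b in zip(edges[:-1], edges[1:]):
        g = float(G(a))
        secreting = g > p.h
        dY_gain = p.alpha * p.beta * (g - p.h) if secreting else 0.0

        def rhs(t, y):
            Y, X, I, CP = y[0], y[1], y[2], y[3]
            v = p.m * X if secreting else 0.0
            ft = float(f(t))
            return (
                dY_gain - p.alpha * Y,
                Y - v,
                p.k_ratio * v - p.k_Iout * (I - p.I_b) + ft,
                v - p.k_CPout * (CP - p.CP_b),
                v,
                I - p.I_b,
                CP - p.CP_b,
                ft,
            )

        t_eval = all_times[(all_times > a + 1e-12) & (all_times <= b + 1e-12)]
        if t_eval.size == 0 or abs(t_eval[-1] - b) > 1e-9:
            t_eval = np.append(t_eval, b)
        sol = solve_ivp(rhs, (a, b), y0, method="RK45", t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed on [{a}, {b}] with params {params}: {sol.message}"
            )
        out.extend(sol.y.T)
        times_out.extend(sol.t)
        y0 = sol.y[:, -1]

    arr = np.asarray(out)
    times = np.asarray(times_out)
    # segment edges are emitted once; keep unique grid times
    uniq = np.concatenate([[True], np.diff(times) > 1e-12])
    arr, times = arr[uniq], times[uniq]
    return Trajectory(
        times=times,
        Y=arr[:, 0],
        X=arr[:, 1],
        I=arr[:, 2],
        CP=arr[:, 3],
        integrals={
            "int_v": arr[:, 4],
            "int_I_dev": arr[:, 5],
            "int_CP_dev": arr[:, 6],
            "int_f": arr[:, 7],
        },
        params=params,
    )


def mass_balance(traj: Trajectory) -> tuple[float, float, float]:
    """Consistency totals over the simulated horizon.

    Returns (secreted_total, cp_accounted, insulin_accounted) where
    cp_accounted = (CP(T)-CP_b) + k_CPout*int(CP-CP_b) must equal the total
    secretion, and insulin_accounted = (I(T)-I_b) + k_Iout*int(I-I_b) - int(f)
    must equal k_ratio times the total secretion (equimolar secretion, hepatic
    extraction of insulin only).
    """
    p = traj.params
    secreted = float(traj.integrals["int_v"][-1])
    cp_acc = float(traj.CP[-1] - p.CP_b + p.k_CPout * traj.integrals["int_CP_dev"][-1])
    i_acc = float(
        traj.I[-1]
        - p.I_b
        + p.k_Iout * traj.integrals["int_I_dev"][-1]
        - traj.integrals["int_f"][-1]
    )
    return secreted, cp_acc, i_acc
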