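"""Logarithmic parameter sensitivity of ipeak and iTPI, cohort medians, and
2^-1..2^1 parameter sweeps.

Sensitivities are evaluated on the hyperglycemic-clamp window (0-90 min) with
no insulin infusion, on a 1-min simulation grid:

    S(f, x) = d log f / d log x ~ (x / f(x)) * (f(1.1x) - f(0.9x)) / (0.2x)

for the six parameters that shape the serum insulin curve (alpha, beta, h, m,
k_ratio, k_Iout; the stored-pool size and C-peptide clearance are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indices import PeakIndices, peak_indices
from .model import ModelParameters, simulate
from .stats import rank_sum_test
from .units import GlucoseInput, ZERO_INFUSION

SENSITIVITY_PARAMS = ("alpha", "beta", "h", "m", "k_ratio", "k_Iout")
SWEEP_FACTORS = 2.0 ** np.array([-1.0, -0.5, 0.0, 0.5, 1.0])


def hgc_indices(
    params: ModelParameters,
    G: GlucoseInput,
    t_end: float = 90.0,
    grid_step: float = 1.0,
) -> PeakIndices:
    """ipeak/iTPI of the simulated insulin curve over the hyperglycemic clamp."""
    traj = simulate(params, G, ZERO_INFUSION, t_end=t_end, grid_step=grid_step)
    return peak_indices(traj.times, traj.I, I0=params.I_b)


def log_sensitivity(
    params: ModelParameters,
    G: GlucoseInput,
    target: str,
    param_name: str,
    grid_step: float = 1.0,
) -> float:
    """Central-difference log-sensitivity of ipeak or iTPI at +/-10% of the
    parameter. NaN when the index is undefined at any evaluation point."""
    if target not in ("ipeak", "iTPI"):
        raise ValueError(f"target must be 'ipeak' or 'iTPI', got {target!r}")
    vals = []
    for factor in (0.9, 1.0, 1.1):
        pi = hgc_indices(params.scaled(param_name, factor), G, grid_step=grid_step)
        if not pi.defined:
            return np.nan
        vals.append(getattr(pi, target))
    f_lo, f_mid, f_hi = vals
    if f_mid == 0:
        return np.nan
    return float((f_hi - f_lo) / (0.2 * f_mid))


@dataclass
class SensitivityResult:
    """Per-subject sensitivities and cohort medians per (target, parameter)."""

    per_subject: pd.DataFrame  # columns: subject, target, parameter, S
    tables: dict = field(default_factory=dict)  # target -> ranked DataFrame

    def table(self, target: str) -> pd.DataFrame:
        return self.tables[target]


def cohort_sensitivity(
    subjects: list[tuple[str, ModelParameters, GlucoseInput]],
    grid_step: float = 1.0,
) -> SensitivityResult:
    """Median log-sensitivity across subjects, ranked by |median|, with a
    two-sided rank-sum P value of each parameter's per-subject distribution
    against the top-ranked parameter's."""
    rows = []
    for sid, params, G in subjects:
        for target in ("ipeak", "iTPI"):
            for name in SENSITIVITY_PARAMS:
                s = log_sensitivity(params, G, target, name, grid_step=grid_step)
                rows.append({"subject": sid, "target": target, "parameter": name, "S": s})
    per_subject = pd.DataFrame(rows)

    tables = {}
    for target in ("ipeak", "iTPI"):
        sub = per_subject[per_subject.target == target]
        med = sub.groupby("parameter")["S"].median().dropna()
        if med.empty:
            raise ValueError(f"all sensitivities undefined for target {target}")
        order = med.abs().sort_values(ascending=False).index
        top = order[0]
        top_vals = sub[sub.parameter == top]["S"].dropna().to_numpy()
        recs = []
        for rank, name in enumerate(order, start=1):
            vals = sub[sub.parameter == name]["S"].dropna().to_numpy()
            if name == top:
                p = np.nan
            else:
                _, p = rank_sum_test(top_vals, vals)
            recs.append(
                {"rank": rank, "parameter": name, "median": med[name], "p_vs_top": p}
            )
        tables[target] = pd.DataFrame(recs)
    return SensitivityResult(per_subject=per_subject, tables=tables)


@dataclass
class SweepResult:
    factors: np.ndarray
    which: str
    trajectories: list
    ipeak: np.ndarray
    iTPI: np.ndarray
    defined: np.ndarray


def parameter_sweep(
    params: ModelParameters,
    G: GlucoseInput,
    which: str = "k_ratio",
    factors=SWEEP_FACTORS,
    t_end: float = 90.0,
    grid_step: float = 1.0,
) -> SweepResult:
    """Scale k_ratio, k_Iout or both by each factor and record the
    hyperglycemic-clamp insulin trajectory and its indices. Scaled k_ratio may
    exceed 1 here (sweep-only relaxation of the estimation bound)."""
    if which not in ("k_ratio", "k_Iout", "both"):
        raise ValueError(f"which must be 'k_ratio', 'k_Iout' or 'both', got {which!r}")
    names = ("k_ratio", "k_Iout") if which == "both" else (which,)
    factors = np.asarray(factors, dtype=float)
    trajs, peaks, tpis, defined = [], [], [], []
    for factor in factors:
        p = params
        for name in names:
            p = p.scaled(name, factor)
        traj = simulate(p, G, ZERO_INFUSION, t_end=t_end, grid_step=grid_step)
        pi = peak_indices(traj.times, traj.I, I0=params.I_b)
        trajs.append(traj)
        peaks.append(pi.ipeak)
        tpis.append(pi.iTPI)
        defined.append(pi.defined)
    return SweepResult(
        factors=factors,
        which=which,
        trajectories=trajs,
        ipeak=np.array(peaks),
        iTPI=np.array(tpis),
        defined=np.array(defined),
    )
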