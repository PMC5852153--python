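"""Robust outlier screening: medcouple and projection-based adjusted
outlyingness (AO) with skew-adjusted boxplot whiskers.

The medcouple uses the O(n^2) kernel-median definition (cohorts here are at
most a few hundred subjects). AO projects the point cloud onto unit directions
through random point pairs and takes, per point, the maximum over directions of
the one-sided distance from the projection median scaled by the adjusted-
boxplot whisker on that side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def medcouple(sample) -> float:
    """Robust skewness in [-1, 1]: median of the kernel
    h(xi, xj) = ((xj - med) - (med - xi)) / (xj - xi) over xi <= med <= xj,
    with the standard signed kernel for observations tied at the median."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("medcouple requires at least 3 points")
    med = float(np.median(x))
    upper = x[x >= med]  # ascending
    lower = x[x <= med]  # ascending
    zu = upper - med
    zl = lower - med
    num = zu[:, None] + zl[None, :]
    den = zu[:, None] - zl[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        h = num / den
    # ties at the median: zu[i] == zl[j] == 0. With k tied values, the kernel
    # is -1 below the anti-diagonal of the k x k tie block, 0 on it, +1 above
    # (indices taken in opposite sort orders for the two factors).
    ku = int(np.sum(zu == 0.0))  # first ku entries of zu
    kl = int(np.sum(zl == 0.0))  # last kl entries of zl
    if ku:
        iu = np.arange(ku)[:, None]  # 0..ku-1 within upper ties
        jl = np.arange(kl)[None, ::-1]  # reversed within lower ties
        block = np.sign(iu - jl)
        h[:ku, -kl:] = block
    return float(np.median(h))


def adjusted_boxplot_whiskers(sample) -> tuple[float, float]:
    """(w_lo, w_up) fences of the medcouple-adjusted boxplot:
    [Q1 - 1.5*e^{-4MC}*IQR, Q3 + 1.5*e^{3MC}*IQR] for MC >= 0, mirrored
    exponents for MC < 0."""
    x = np.asarray(sample, dtype=float)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    mc = medcouple(x)
    if mc >= 0:
        lo_e, hi_e = -4.0 * mc, 3.0 * mc
    else:
        lo_e, hi_e = -3.0 * mc, 4.0 * mc
    return float(q1 - 1.5 * np.exp(lo_e) * iqr), float(q3 + 1.5 * np.exp(hi_e) * iqr)


def _projection_outlyingness(z: np.ndarray) -> np.ndarray:
    """Per-point outlyingness of a 1-D projection."""
    med = float(np.median(z))
    w_lo, w_up = adjusted_boxplot_whiskers(z)
    up_scale = w_up - med
    lo_scale = med - w_lo
    out = np.zeros_like(z)
    hi = z > med
    if up_scale > 0:
        out[hi] = (z[hi] - med) / up_scale
    lo = z < med
    if lo_scale > 0:
        out[lo] = (med - z[lo]) / lo_scale
    return out


def adjusted_outlyingness(
    points, n_directions: int = 8000, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """AO per point: max over seeded random directions (unit vectors through
    data point pairs) of the per-projection outlyingness. Directions with zero
    projected variance are skipped."""
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = X.shape
    if n < 4:
        raise ValueError("adjusted outlyingness requires at least 4 points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ao = np.zeros(n)
    drawn = 0
    attempts = 0
    max_attempts = 20 * n_directions
    while drawn < n_directions and attempts < max_attempts:
        batch = min(n_directions - drawn, 1024)
        attempts += batch
        i = rng.integers(0, n, size=batch)
        j = rng.integers(0, n, size=batch)
        v = X[i] - X[j]
        norms = np.linalg.norm(v, axis=1)
        keep = norms > 1e-12
        v = v[keep] / norms[keep, None]
        for vk in v:
            z = X @ vk
            if np.ptp(z) <= 1e-12:
                continue
            ao = np.maximum(ao, _projection_outlyingness(z))
            drawn += 1
            if drawn >= n_directions:
                break
    return ao


@dataclass
class OutlierReport:
    ao_values: np.ndarray
    cutoff: float
    flagged: list

    def to_frame(self, subject_ids=None):
        import pandas as pd

        ids = list(subject_ids) if subject_ids is not None else list(range(len(self.ao_values)))
        return pd.DataFrame(
            {
                "subject_id": ids,
                "ao": self.ao_values,
                "cutoff": self.cutoff,
                "flagged": [i in set(self.flagged) for i in range(len(self.ao_values))],
            }
        )


def flag_outliers(ao_values) -> OutlierReport:
    """Flag AO values above Q3 + 1.5*e^{3MC}*IQR, cutoff computed on the AO
    distribution itself."""
    ao = np.asarray(ao_values, dtype=float)
    if ao.size < 4:
        raise ValueError("need at least 4 AO values")
    q1, q3 = np.quantile(ao, [0.25, 0.75])
    mc = medcouple(ao) if np.ptp(ao) > 0 else 0.0
    cutoff = float(q3 + 1.5 * np.exp(3.0 * mc) * (q3 - q1))
    flagged = list(np.nonzero(ao > cutoff)[0])
    return OutlierReport(ao_values=ao, cutoff=cutoff, flagged=flagged)
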