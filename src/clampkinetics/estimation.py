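"""Per-subject parameter estimation.

The objective is the normalized residual sum of squares over the 9 insulin and
9 C-peptide sampling points. Each restart runs a self-adaptive evolutionary
programming (EP) search over log10-transformed parameters inside the bounding
box, followed by bounded trust-region least squares to reach the local
minimum; the best restart by RSS wins (ties broken by lowest restart index).

A structural subtlety shapes the local stage: secretion switches on only while
G(t) > h, so the objective is *piecewise* smooth in the threshold h, with
discontinuities wherever h crosses one of the subject's observed glucose
levels. Gradient-based refinement therefore constrains h to its current
smooth piece (between adjacent observed glucose values) and profiles the
neighboring pieces explicitly; the EP phase, which needs no gradients, roams
the full box. The local stage additionally polishes the EP run's improvement
archive and a few seeded auxiliary starts, which guards against the deceptive
basins this switch structure creates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import fastsim
from .data import SubjectRecord
from .model import PARAM_NAMES, ModelParameters
from .units import GlucoseInput, InfusionFunction

_PENALTY = 1e100
_H_INDEX = PARAM_NAMES.index("h")


@dataclass(frozen=True)
class NormalizationMeans:
    """Cohort-wide mean serum concentrations used to normalize residuals."""

    I_mean: float
    CP_mean: float

    def __post_init__(self) -> None:
        if self.I_mean <= 0 or self.CP_mean <= 0:
            raise ValueError("normalization means must be strictly positive")


#: Cohort constants reported for the original 121-subject study.
PAPER_MEANS = NormalizationMeans(I_mean=302.7, CP_mean=1475.0)


def rss(measured_I, measured_CP, sim_I, sim_CP, means: NormalizationMeans) -> float:
    """Sum of squared normalized residuals over both species."""
    mi, mc = np.asarray(measured_I, float), np.asarray(measured_CP, float)
    si, sc = np.asarray(sim_I, float), np.asarray(sim_CP, float)
    if mi.shape != si.shape or mc.shape != sc.shape:
        raise ValueError("measured and simulated series must have equal lengths")
    return float(
        np.sum(((mi - si) / means.I_mean) ** 2) + np.sum(((mc - sc) / means.CP_mean) ** 2)
    )


def cohort_means(records: list[SubjectRecord]) -> NormalizationMeans:
    """Grand mean over all subjects and all sampling points, per species
    (pooled, weighted by point count — not a mean of subject means)."""
    if not records:
        raise ValueError("cohort_means requires at least one subject")
    i_all = np.concatenate([r.insulin for r in records])
    cp_all = np.concatenate([r.cpeptide for r in records])
    if i_all.size == 0:
        raise ValueError("cohort_means requires at least one sampling point")
    return NormalizationMeans(I_mean=float(i_all.mean()), CP_mean=float(cp_all.mean()))


@dataclass(frozen=True)
class ParamRestriction:
    """A candidate model expressed as a restriction of the full 8-parameter
    vector: entries with free_mask True are estimated, the rest pinned."""

    free_mask: np.ndarray
    fixed_values: np.ndarray

    @classmethod
    def full(cls) -> "ParamRestriction":
        return cls(np.ones(8, dtype=bool), np.full(8, np.nan))

    @classmethod
    def fixing(cls, **fixed: float) -> "ParamRestriction":
        mask = np.ones(8, dtype=bool)
        vals = np.full(8, np.nan)
        for name, value in fixed.items():
            i = PARAM_NAMES.index(name)
            mask[i] = False
            vals[i] = value
        return cls(mask, vals)

    @property
    def n_free(self) -> int:
        return int(self.free_mask.sum())

    @property
    def h_free_index(self) -> int | None:
        """Position of h within the free vector, or None if h is pinned."""
        if not self.free_mask[_H_INDEX]:
            return None
        return int(self.free_mask[:_H_INDEX].sum())

    def expand(self, x_free: np.ndarray) -> np.ndarray:
        """Map (n, n_free) free-parameter rows to (n, 8) full vectors."""
        x_free = np.atleast_2d(x_free)
        out = np.tile(self.fixed_values, (x_free.shape[0], 1))
        out[:, self.free_mask] = x_free
        return out


@dataclass
class EstimationConfig:
    """Search configuration.

    Bounds follow the 1e-6..1e4 box with k_ratio capped at 1. ``test_scale``
    (100 parents / 500 generations / 5 restarts) keeps a desk-size cohort
    tractable; ``paper_scale`` mirrors the original 400/4000/20 settings.
    """

    bounds_low: float = 1e-6
    bounds_high: float = 1e4
    k_ratio_max: float = 1.0
    n_parents: int = 100
    n_generations: int = 500
    n_restarts: int = 5
    rng_seed: int = 0
    normalization: str = "cohort_means"
    tournament_q: int = 10
    search_dt: float = 0.5
    refine_dt: float = 0.1
    t_end: float = 220.0
    # EP mutation kernel: heavy-tailed steps with a step-size floor keep the
    # population exploring; the local stage does the fine convergence.
    ep_cauchy: bool = True
    ep_sigma_init: float = 0.25
    ep_sigma_floor: float = 0.02
    # local stage: h-piece profiling breadth and seeded auxiliary starts
    profile_topk: int = 4
    profile_rounds: int = 2
    n_aux_starts: int = 5
    n_archive_starts: int = 2

    def __post_init__(self) -> None:
        if min(self.n_parents, self.n_generations + 1, self.n_restarts) < 1:
            raise ValueError("population counts must be >= 1")
        if self.bounds_low >= self.bounds_high:
            raise ValueError("bounds_low must be < bounds_high")

    @classmethod
    def test_scale(cls, **kw) -> "EstimationConfig":
        return cls(n_parents=100, n_generations=500, n_restarts=5, **kw)

    @classmethod
    def paper_scale(cls, **kw) -> "EstimationConfig":
        return cls(n_parents=400, n_generations=4000, n_restarts=20, **kw)

    def log_bounds(self, restriction: ParamRestriction) -> tuple[np.ndarray, np.ndarray]:
        lo = np.full(8, np.log10(self.bounds_low))
        hi = np.full(8, np.log10(self.bounds_high))
        hi[PARAM_NAMES.index("k_ratio")] = np.log10(self.k_ratio_max)
        return lo[restriction.free_mask], hi[restriction.free_mask]


@dataclass
class FitResult:
    params: ModelParameters
    rss: float
    per_restart: list = field(default_factory=list)
    best_restart_index: int = 0
    n_points: int = 18
    converged: bool = True
    seed_info: tuple = ()

    def to_dict(self) -> dict:
        d = {name: getattr(self.params, name) for name in PARAM_NAMES}
        d.update(
            rss=self.rss,
            best_restart=self.best_restart_index,
            n_restarts=len(self.per_restart),
        )
        return d


def evolutionary_search(
    objective,
    bounds: tuple[np.ndarray, np.ndarray],
    n_parents: int,
    n_generations: int,
    rng: np.random.Generator,
    tournament_q: int = 10,
    cauchy: bool = False,
    sigma_init: float = 0.2,
    sigma_floor: float = 1e-5,
    return_archive: bool = False,
):
    """Self-adaptive EP minimization of a vectorized objective over a box.

    Each parent spawns one offspring by log-normal mutation of its per-
    coordinate step sizes followed by Gaussian (or, with ``cauchy=True``,
    heavy-tailed) mutation of its position; survivors are chosen by q-opponent
    tournament over parents+offspring. Deterministic given the generator
    state. Returns the best point ever evaluated, optionally with the archive
    of successive best-so-far improvements.
    """
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    d = lo.size
    span = hi - lo
    tau_p = 1.0 / np.sqrt(2.0 * d)
    tau = 1.0 / np.sqrt(2.0 * np.sqrt(d))

    def evaluate(x):
        f = np.asarray(objective(x), dtype=float)
        bad = ~np.isfinite(f)
        if bad.mean() > 0.5:
            raise RuntimeError(
                f"objective non-finite for {bad.sum()}/{bad.size} of a generation"
            )
        f[bad] = _PENALTY
        return f

    x = lo + rng.random((n_parents, d)) * span
    sigma = np.tile(span * sigma_init, (n_parents, 1))
    f = evaluate(x)
    i_best = int(np.argmin(f))
    archive = [(x[i_best].copy(), float(f[i_best]))]

    for _ in range(n_generations):
        common = rng.standard_normal((n_parents, 1))
        sig_off = sigma * np.exp(tau_p * common + tau * rng.standard_normal((n_parents, d)))
        np.clip(sig_off, sigma_floor * span, span, out=sig_off)
        step = (
            rng.standard_cauchy((n_parents, d)) if cauchy
            else rng.standard_normal((n_parents, d))
        )
        x_off = np.clip(x + sig_off * step, lo, hi)
        f_off = evaluate(x_off)

        xu = np.vstack([x, x_off])
        su = np.vstack([sigma, sig_off])
        fu = np.concatenate([f, f_off])
        i = int(np.argmin(fu))
        if fu[i] < archive[-1][1]:
            archive.append((xu[i].copy(), float(fu[i])))

        opponents = rng.integers(0, 2 * n_parents, size=(2 * n_parents, tournament_q))
        wins = (fu[:, None] <= fu[opponents]).sum(axis=1)
        order = np.lexsort((fu, -wins))[:n_parents]
        x, sigma, f = xu[order], su[order], fu[order]

    best_x, best_f = archive[-1]
    if return_archive:
        return best_x, best_f, archive
    return best_x, best_f


def refine_local(
    x0: np.ndarray,
    residual_fn,
    bounds: tuple[np.ndarray, np.ndarray],
    h_index: int | None = None,
    h_edges: np.ndarray | None = None,
    max_nfev: int = 400,
) -> tuple[np.ndarray, float, bool]:
    """Bounded least squares from x0; never returns a worse RSS than x0.

    When ``h_index``/``h_edges`` identify the glucose-threshold coordinate and
    the (log10) piece edges, h is constrained to the smooth piece containing
    x0 so the trust-region model never straddles a switch discontinuity.
    """
    lo, hi = np.asarray(bounds[0], float).copy(), np.asarray(bounds[1], float).copy()
    x0 = np.clip(np.asarray(x0, float), lo, hi)
    if h_index is not None and h_edges is not None and h_edges.size >= 2:
        p = int(np.clip(np.searchsorted(h_edges, x0[h_index], side="right") - 1,
                        0, h_edges.size - 2))
        lo[h_index] = max(lo[h_index], h_edges[p] + 1e-9)
        hi[h_index] = min(hi[h_index], h_edges[p + 1] - 1e-9)
        x0 = np.clip(x0, lo, hi)
    r0 = residual_fn(x0)
    rss0 = float(np.dot(r0, r0))
    try:
        sol = least_squares(
            residual_fn, x0, bounds=(lo, hi), method="trf", diff_step=1e-6,
            xtol=1e-11, ftol=1e-11, gtol=1e-11, max_nfev=max_nfev,
        )
    except Exception:
        return x0, rss0, False
    rss1 = float(2.0 * sol.cost)
    if not np.isfinite(rss1) or rss1 > rss0:
        return x0, rss0, False
    return sol.x, rss1, bool(sol.success)


class SubjectObjective:
    """Normalized-RSS objective for one subject, over log10 free parameters."""

    def __init__(
        self,
        record: SubjectRecord,
        G: GlucoseInput,
        f: InfusionFunction,
        means: NormalizationMeans,
        config: EstimationConfig,
        restriction: ParamRestriction | None = None,
    ):
        self.record = record
        self.means = means
        self.restriction = restriction or ParamRestriction.full()
        self.I_b = record.meta.fasting_insulin
        self.CP_b = record.meta.fasting_cpeptide
        self._grids = {}
        for dt in (config.search_dt, config.refine_dt):
            g_steps, f_avg, _ = fastsim.prepare_forcing(G, f, dt, config.t_end)
            samp = fastsim.sample_indices(record.sample_times, dt)
            self._grids[dt] = (g_steps, f_avg, samp)
        self.search_dt = config.search_dt
        self.refine_dt = config.refine_dt
        self._wi = 1.0 / means.I_mean
        self._wc = 1.0 / means.CP_mean
        # log10 edges of the smooth pieces of the threshold h: the observed
        # glucose levels partition the box into intervals with a constant
        # secretion-switch pattern
        g_vals = np.unique(np.round(self._grids[config.refine_dt][0], 9))
        lo, hi = config.bounds_low, config.bounds_high
        inside = g_vals[(g_vals > lo) & (g_vals < hi)]
        self.h_edges = np.log10(np.concatenate([[lo], inside, [hi]]))

    def _simulate(self, x_log: np.ndarray, dt: float):
        theta = self.restriction.expand(10.0 ** np.atleast_2d(x_log))
        g_steps, f_avg, samp = self._grids[dt]
        return fastsim.simulate_population(theta, self.I_b, self.CP_b, g_steps, f_avg, samp, dt)

    def population_rss(self, x_log: np.ndarray) -> np.ndarray:
        I, CP = self._simulate(x_log, self.search_dt)
        ri = (I - self.record.insulin) * self._wi
        rc = (CP - self.record.cpeptide) * self._wc
        return np.einsum("ij,ij->i", ri, ri) + np.einsum("ij,ij->i", rc, rc)

    def residual(self, x_log: np.ndarray) -> np.ndarray:
        I, CP = self._simulate(x_log, self.refine_dt)
        return np.concatenate(
            [
                (I[0] - self.record.insulin) * self._wi,
                (CP[0] - self.record.cpeptide) * self._wc,
            ]
        )

    def rss_at(self, x_log: np.ndarray) -> float:
        r = self.residual(x_log)
        return float(np.dot(r, r))


def refine_profiled(
    obj: SubjectObjective,
    x0: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    topk: int = 5,
    rounds: int = 3,
) -> tuple[np.ndarray, float, bool]:
    """In-piece refinement plus an explicit profile over the h pieces.

    After refining within the start's own piece, the objective is scanned at
    each piece midpoint (holding the other parameters), and the most promising
    pieces are refined in turn until no piece improves the fit.
    """
    hi_idx = obj.restriction.h_free_index
    edges = obj.h_edges
    x_best, f_best, conv = refine_local(x0, obj.residual, bounds,
                                        h_index=hi_idx, h_edges=edges)
    if hi_idx is None:
        return x_best, f_best, conv
    mids = 0.5 * (edges[:-1] + edges[1:])
    for _ in range(rounds):
        scan = np.empty(mids.size)
        for p in range(mids.size):
            xt = x_best.copy()
            xt[hi_idx] = mids[p]
            scan[p] = obj.rss_at(xt)
        p_cur = int(np.clip(np.searchsorted(edges, x_best[hi_idx], side="right") - 1,
                            0, mids.size - 1))
        improved = False
        for p in np.argsort(scan)[:topk]:
            if p == p_cur:
                continue
            xt = x_best.copy()
            xt[hi_idx] = mids[p]
            x, f, c = refine_local(xt, obj.residual, bounds,
                                   h_index=hi_idx, h_edges=edges)
            if f < f_best:
                x_best, f_best, conv, improved = x, f, c, True
        if not improved:
            break
    return x_best, f_best, conv


def heuristic_start(
    obj: SubjectObjective,
    bounds: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """A jittered, data-driven starting point in log10 space.

    Reads crude rate estimates off the subject's own series: C-peptide decay
    after secretion shuts off gives k_CPout; the second-phase quasi-steady
    state ties the secretion flux to beta and couples k_ratio to k_Iout; the
    first-phase C-peptide rise sizes the stored pool. Only meaningful for the
    full 8-parameter model; restricted candidates fall back to a random draw.
    """
    lo, hi = bounds
    r = obj.record
    if obj.restriction.n_free != 8 or r.sample_times.size < 6:
        return lo + rng.random(lo.size) * (hi - lo)
    t = r.sample_times
    I, CP = r.insulin, r.cpeptide
    I_b, CP_b = obj.I_b, obj.CP_b
    jit = lambda: np.exp(0.25 * rng.standard_normal())

    d1, d2 = CP[-2] - CP_b, CP[-1] - CP_b
    if d1 > 0 and d2 > 0 and d1 > d2:
        k_cp = np.log(d1 / d2) / (t[-1] - t[-2])
    else:
        k_cp = 0.05
    k_cp = float(np.clip(k_cp * jit(), 1e-3, 1.0))

    h0 = max(r.meta.fasting_glucose, 1e-3) * jit()
    # quasi-steady second phase around t ~ 90
    i90 = int(np.argmin(np.abs(t - 90.0)))
    cp_dev = max(CP[i90] - CP_b, 1.0)
    i_dev = max(I[i90] - I_b, 0.1)
    v_ss = k_cp * cp_dev
    g_excess = max(np.max(r.glucose_values) - h0, 0.5) if r.glucose_values.size else 5.0
    beta0 = max(v_ss / g_excess, 1e-4) * jit()
    # first-phase C-peptide rise sizes the stored pool
    i10 = int(np.argmin(np.abs(t - 10.0)))
    X_b0 = max((CP[i10] - CP_b) / 0.8, 10.0) * jit()
    m0 = 0.2 * jit()
    k_i = float(np.exp(rng.uniform(np.log(0.03), np.log(0.5))))
    k_ratio0 = float(np.clip(k_i * i_dev / max(v_ss, 1e-6), 1e-3, 1.0))
    theta = np.array([0.05 * jit(), beta0, h0, m0, X_b0, k_ratio0, k_i, k_cp])
    return np.clip(np.log10(theta), lo, hi)


def subject_seed_key(subject_id: str) -> int:
    return zlib.crc32(subject_id.encode("utf-8")) & 0x7FFFFFFF


def fit_subject(
    record: SubjectRecord,
    G: GlucoseInput,
    f: InfusionFunction,
    config: EstimationConfig,
    means: NormalizationMeans | None = None,
    restriction: ParamRestriction | None = None,
) -> FitResult:
    """Multi-restart EP + local refinement for one subject.

    Restart seeds derive from (config.rng_seed, crc32(subject_id), restart), so
    subjects are fitted independently and reproducibly regardless of cohort
    order. ``means`` defaults to the original study's cohort constants; pass
    ``cohort_means(records)`` to renormalize against the data at hand.
    """
    if record.sample_times.size < 1:
        raise ValueError("record has no sampling points")
    if means is None:
        means = PAPER_MEANS
    restriction = restriction or ParamRestriction.full()
    obj = SubjectObjective(record, G, f, means, config, restriction)
    bounds = config.log_bounds(restriction)
    lo, hi = bounds
    key = subject_seed_key(record.meta.subject_id)

    per_restart = []
    errors = []
    for r in range(config.n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, key, r]))
        try:
            _, _, archive = evolutionary_search(
                obj.population_rss,
                bounds,
                config.n_parents,
                config.n_generations,
                rng,
                tournament_q=config.tournament_q,
                cauchy=config.ep_cauchy,
                sigma_init=config.ep_sigma_init,
                sigma_floor=config.ep_sigma_floor,
                return_archive=True,
            )
            starts = [x for x, _ in archive[-config.n_archive_starts:]]
            n_heur = (config.n_aux_starts + 1) // 2
            starts += [heuristic_start(obj, bounds, rng) for _ in range(n_heur)]
            starts += [
                lo + rng.random(lo.size) * (hi - lo)
                for _ in range(config.n_aux_starts - n_heur)
            ]
            best = None
            for x0 in starts:
                x, f_val, conv = refine_profiled(
                    obj, x0, bounds, topk=config.profile_topk, rounds=config.profile_rounds
                )
                if best is None or f_val < best[1]:
                    best = (x, f_val, conv)
                if best[1] < 1e-8:  # already at the noiseless floor
                    break
            # deep polish of the restart's winner
            x, f_val, conv = refine_local(
                best[0], obj.residual, bounds, h_index=obj.restriction.h_free_index,
                h_edges=obj.h_edges, max_nfev=2000,
            )
            if f_val < best[1]:
                best = (x, f_val, conv)
        except Exception as exc:  # noqa: BLE001 - diagnostics aggregated below
            errors.append(f"restart {r}: {exc!r}")
            continue
        x_fit, rss_fit, conv = best
        theta = restriction.expand(10.0 ** x_fit)[0]
        params = ModelParameters.from_array(theta, record.meta.fasting_insulin,
                                            record.meta.fasting_cpeptide)
        per_restart.append((params, rss_fit, conv))

    if not per_restart:
        raise RuntimeError(
            f"all restarts failed for subject {record.meta.subject_id}: {errors}"
        )
    best_idx = min(range(len(per_restart)), key=lambda i: (per_restart[i][1], i))
    best_params, best_rss, best_conv = per_restart[best_idx]
    return FitResult(
        params=best_params,
        rss=best_rss,
        per_restart=per_restart,
        best_restart_index=best_idx,
        n_points=record.sample_times.size * 2,
        converged=best_conv,
        seed_info=(config.rng_seed, key),
    )
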