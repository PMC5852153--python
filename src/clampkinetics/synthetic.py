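"""Synthetic clamp cohorts with group-structured parameter distributions.

The generator emulates the consecutive-clamp design: a hyperglycemic clamp
holding plasma glucose near 200 mg/dL over 0-90 min, a 10-min gap, then a
hyperinsulinemic-euglycemic clamp (insulin at 40 mU/m^2/min, glucose near
90 mg/dL or the fasting level if lower) over 100-220 min, with serum insulin
and C-peptide observed at the nine clinical sampling times under
multiplicative assay-like noise.

Model parameters are drawn log-normally per glycemic group. The default group
medians are design choices tuned once so that the simulated mean curves show
the qualitative clinical picture: blunted first- and second-phase secretion in
T2DM, a higher glucose threshold and smaller stored pool in T2DM, higher
peripheral insulin clearance (k_Iout) and lower hepatic extraction
(1 - k_ratio) in normal glucose tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GROUPS, SAMPLING_TIMES, SubjectMeta, SubjectRecord
from .model import ModelParameters, Trajectory, simulate
from .units import (
    GlucoseInput,
    InfusionFunction,
    body_surface_area,
    build_glucose_input,
    convert_iir_to_cIIR,
    convert_units,
)

#: Plateau targets in mM.
HGC_TARGET = convert_units(200.0, "glucose_mgdl_to_mM")  # ~11.101
HEC_TARGET = convert_units(90.0, "glucose_mgdl_to_mM")  # ~4.996


@dataclass(frozen=True)
class LogNormalSpec:
    median: float
    sigma: float  # scale of ln; 0 collapses to the median

    def draw(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        if self.sigma == 0:
            return np.full(n, self.median)
        return self.median * np.exp(self.sigma * rng.standard_normal(n))


@dataclass(frozen=True)
class GroupProfile:
    """Log-normal location/scale per model parameter plus basal and
    anthropometric distributions for one glycemic group."""

    name: str
    params: dict  # parameter name -> LogNormalSpec
    fasting_insulin: LogNormalSpec
    fasting_cpeptide: LogNormalSpec
    fasting_glucose: LogNormalSpec
    weight: LogNormalSpec = LogNormalSpec(64.0, 0.15)
    height_mean: float = 165.0
    height_sd: float = 8.0
    female_fraction: float = 0.5


def _profile(name, beta, h, X_b, k_ratio, k_Iout, I_b, CP_b, fpg) -> GroupProfile:
    return GroupProfile(
        name=name,
        params={
            "alpha": LogNormalSpec(0.05, 0.30),
            "beta": LogNormalSpec(beta, 0.25),
            "h": LogNormalSpec(h, 0.05),
            "m": LogNormalSpec(0.20, 0.25),
            "X_b": LogNormalSpec(X_b, 0.25),
            "k_ratio": LogNormalSpec(k_ratio, 0.18),
            "k_Iout": LogNormalSpec(k_Iout, 0.15),
            "k_CPout": LogNormalSpec(0.05, 0.20),
        },
        fasting_insulin=LogNormalSpec(I_b, 0.30),
        fasting_cpeptide=LogNormalSpec(CP_b, 0.25),
        fasting_glucose=LogNormalSpec(fpg, 0.05),
    )


#: Group medians encode the cohort-level orderings reported clinically:
#: k_Iout(NGT) > k_Iout(borderline) ~ k_Iout(T2DM); hepatic extraction
#: (1 - k_ratio) lowest in NGT; h and X_b shifted in T2DM.
DEFAULT_PROFILES: dict[str, GroupProfile] = {
    "NGT": _profile("NGT", beta=15.0, h=5.0, X_b=2000.0, k_ratio=0.55,
                    k_Iout=0.20, I_b=35.0, CP_b=400.0, fpg=5.0),
    "borderline": _profile("borderline", beta=13.0, h=5.8, X_b=1700.0, k_ratio=0.42,
                           k_Iout=0.11, I_b=55.0, CP_b=550.0, fpg=5.9),
    "T2DM": _profile("T2DM", beta=10.0, h=7.0, X_b=900.0, k_ratio=0.38,
                     k_Iout=0.10, I_b=50.0, CP_b=500.0, fpg=7.3),
}

_BOUNDS = (1e-6, 1e4)


def sample_parameters(
    profile: GroupProfile,
    n: int,
    seed: int | np.random.Generator = 0,
    basal: bool = True,
) -> list[ModelParameters]:
    """i.i.d. parameter draws; k_ratio truncated to (0, 1], everything clipped
    into the estimation box."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = {name: spec.draw(rng, n) for name, spec in profile.params.items()}
    draws["k_ratio"] = np.minimum(draws["k_ratio"], 1.0)
    for name in draws:
        draws[name] = np.clip(draws[name], *_BOUNDS)
    I_b = profile.fasting_insulin.draw(rng, n) if basal else np.full(n, np.nan)
    CP_b = profile.fasting_cpeptide.draw(rng, n) if basal else np.full(n, np.nan)
    return [
        ModelParameters(
            alpha=draws["alpha"][i],
            beta=draws["beta"][i],
            h=draws["h"][i],
            m=draws["m"][i],
            X_b=draws["X_b"][i],
            k_ratio=draws["k_ratio"][i],
            k_Iout=draws["k_Iout"][i],
            k_CPout=draws["k_CPout"][i],
            I_b=I_b[i],
            CP_b=CP_b[i],
        )
        for i in range(n)
    ]


def synth_meta(
    profile: GroupProfile, subject_id: str, rng: np.random.Generator
) -> SubjectMeta:
    sex = "female" if rng.random() < profile.female_fraction else "male"
    return SubjectMeta(
        subject_id=subject_id,
        sex=sex,
        weight=float(profile.weight.draw(rng, 1)[0]),
        height=float(np.clip(profile.height_mean + profile.height_sd * rng.standard_normal(),
                             140.0, 200.0)),
        group=profile.name,
        fasting_glucose=float(profile.fasting_glucose.draw(rng, 1)[0]),
        fasting_insulin=float(profile.fasting_insulin.draw(rng, 1)[0]),
        fasting_cpeptide=float(profile.fasting_cpeptide.draw(rng, 1)[0]),
    )


def _glucose_profile(t, fpg: float, eu_target: float):
    """Canonical continuous plasma-glucose time course (mM)."""
    t = np.asarray(t, dtype=float)
    ramp = fpg + (HGC_TARGET - fpg) * np.clip(t / 12.0, 0.0, 1.0)
    decay = eu_target + (HGC_TARGET - eu_target) * np.exp(-(t - 90.0) / 12.0)
    return np.where(t <= 90.0, ramp, decay)


def synth_forcing(
    meta: SubjectMeta,
    seed: int | np.random.Generator = 0,
    noise_scale: float = 1.0,
    k_Iout_hint: float | None = None,
):
    """Clamp forcing for one subject.

    Returns (GlucoseInput, InfusionFunction, traces) where traces is a dict of
    the raw 5-min glucose averages and the IIR / GIR time series the pipeline
    files carry. ``noise_scale`` = 0 gives the deterministic canonical
    profiles; ``k_Iout_hint`` couples the euglycemic glucose-infusion plateau
    to the subject's insulin sensitivity so clinical indices carry signal.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eu_target = min(HEC_TARGET, meta.fasting_glucose)

    g_times = np.arange(5.0, 220.0 + 1e-9, 5.0)
    g_avg = _glucose_profile(g_times - 2.5, meta.fasting_glucose, eu_target)
    g_avg = g_avg * (1.0 + 0.015 * noise_scale * rng.standard_normal(g_avg.size))
    g_avg = np.maximum(g_avg, 0.1)
    G = build_glucose_input(g_times, g_avg, meta.fasting_glucose)

    # insulin infusion: 40 mU/m^2/min with a decaying priming component
    base_iir = 40.0 * body_surface_area(meta.weight, meta.height) / meta.weight
    iir_times = np.arange(101.0, 220.0 + 1e-9, 1.0)
    iir = base_iir * (1.0 + 1.5 * np.exp(-0.15 * (iir_times - 100.0)))
    ciir_base = convert_iir_to_cIIR(base_iir, meta.sex)
    f = InfusionFunction(ii1=1.5 * ciir_base, ii2=-0.15, ii3=ciir_base, onset_time=100.0)

    k_hint = k_Iout_hint if k_Iout_hint is not None else 0.15
    gir_ss = 45.0 * k_hint * np.exp(0.10 * noise_scale * rng.standard_normal())
    gir_times = np.arange(5.0, 220.0 + 1e-9, 5.0)
    gir_hgc = 2.0 + 6.0 * np.exp(-gir_times / 15.0)
    gir_hec = gir_ss * (1.0 - np.exp(-(gir_times - 100.0) / 25.0))
    gir = np.where(gir_times <= 90.0, gir_hgc, np.maximum(gir_hec, 0.0))
    gir = gir * (1.0 + 0.03 * noise_scale * rng.standard_normal(gir.size))
    gir = np.maximum(gir, 0.0)

    traces = {
        "glucose_times": g_times,
        "glucose_values": g_avg,
        "iir_times": iir_times,
        "iir_values": iir,
        "gir_times": gir_times,
        "gir_values": gir,
    }
    return G, f, traces


@dataclass
class SyntheticSubject:
    record: SubjectRecord
    true_params: ModelParameters
    G: GlucoseInput
    f: InfusionFunction
    noiseless_I: np.ndarray
    noiseless_CP: np.ndarray
    trajectory: Trajectory


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    master_seed: int
    noise_cv: float

    @property
    def records(self) -> list[SubjectRecord]:
        return [s.record for s in self.subjects]

    def truth_frame(self):
        import pandas as pd

        from .model import PARAM_NAMES

        rows = []
        for s in self.subjects:
            row = {"subject_id": s.record.meta.subject_id, "group": s.record.meta.group}
            row.update({n: getattr(s.true_params, n) for n in PARAM_NAMES})
            row.update(I_b=s.true_params.I_b, CP_b=s.true_params.CP_b)
            rows.append(row)
        return pd.DataFrame(rows)


def generate_cohort(
    profiles: dict[str, GroupProfile] | None = None,
    n_per_group: int | dict = 20,
    noise_cv: float = 0.05,
    master_seed: int = 0,
    grid_step: float = 1.0,
) -> SyntheticCohort:
    """Sample parameters per group, simulate each subject under its clamp
    forcing, and observe serum insulin/C-peptide at the nine sampling times
    with multiplicative Gaussian noise (CV ``noise_cv``) floored at basal.

    Bit-identical regeneration from (profiles, n_per_group, master_seed)."""
    profiles = profiles if profiles is not None else DEFAULT_PROFILES
    subjects: list[SyntheticSubject] = []
    for gi, (gname, profile) in enumerate(profiles.items()):
        n = n_per_group[gname] if isinstance(n_per_group, dict) else n_per_group
        if n < 1:
            continue
        for si in range(n):
            rng = np.random.default_rng(np.random.SeedSequence([master_seed, gi, si]))
            sid = f"{gname}_{si:03d}"
            for _attempt in range(5):
                meta = synth_meta(profile, sid, rng)
                params = sample_parameters(profile, 1, rng)[0].replace(
                    I_b=meta.fasting_insulin, CP_b=meta.fasting_cpeptide
                )
                G, f, traces = synth_forcing(
                    meta, rng, noise_scale=1.0, k_Iout_hint=params.k_Iout
                )
                try:
                    traj = simulate(params, G, f, t_end=220.0, grid_step=grid_step,
                                    sample_times=SAMPLING_TIMES)
                except RuntimeError:
                    continue
                break
            else:
                raise RuntimeError(f"could not simulate a parameter draw for {sid}")
            I_clean, CP_clean = traj.sample(SAMPLING_TIMES)
            obs_I = I_clean * (1.0 + noise_cv * rng.standard_normal(I_clean.size))
            obs_CP = CP_clean * (1.0 + noise_cv * rng.standard_normal(CP_clean.size))
            obs_I = np.maximum(obs_I, meta.fasting_insulin)
            obs_CP = np.maximum(obs_CP, meta.fasting_cpeptide)
            record = SubjectRecord(
                meta=meta,
                sample_times=SAMPLING_TIMES.copy(),
                insulin=obs_I,
                cpeptide=obs_CP,
                **traces,
            )
            subjects.append(
                SyntheticSubject(
                    record=record,
                    true_params=params,
                    G=G,
                    f=f,
                    noiseless_I=I_clean,
                    noiseless_CP=CP_clean,
                    trajectory=traj,
                )
            )
    if not subjects:
        raise ValueError("no subjects generated (all group sizes < 1?)")
    return SyntheticCohort(subjects=subjects, master_seed=master_seed, noise_cv=noise_cv)
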