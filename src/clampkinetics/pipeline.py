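"""End-to-end pipeline stages: generate -> fit -> analyze.

Each stage reads/writes the CSV contracts in :mod:`clampkinetics.io`, records
a JSON run manifest (stage, seeds, input hashes, per-subject status) alongside
its outputs, and derives all randomness from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, selection, stats
from .data import SubjectRecord
from .estimation import EstimationConfig, FitResult, cohort_means, fit_subject, PAPER_MEANS
from .indices import auc_iri10, clamp_di, isi, mcr, peak_indices
from .model import PARAM_NAMES, ModelParameters
from .outliers import adjusted_outlyingness, flag_outliers
from .sensitivity import cohort_sensitivity, parameter_sweep
from .synthetic import DEFAULT_PROFILES, generate_cohort
from .units import build_glucose_input, convert_iir_to_cIIR, convert_units, fit_infusion_function


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    master_seed: int = 0
    n_per_group: int = 6
    noise_cv: float = 0.05
    grid_step: float = 1.0
    normalization: str = "cohort_means"  # or "paper_constants"
    models: tuple = ("model_vi",)
    scale: str = "test"  # "test" or "paper"
    estimation: dict = field(default_factory=dict)

    def estimation_config(self) -> EstimationConfig:
        kw = dict(
            n_parents=400 if self.scale == "paper" else 100,
            n_generations=4000 if self.scale == "paper" else 500,
            n_restarts=20 if self.scale == "paper" else 5,
            rng_seed=self.master_seed,
            normalization=self.normalization,
        )
        kw.update(self.estimation)  # explicit overrides win
        return EstimationConfig(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.scale not in ("test", "paper"):
            raise ValueError(f"scale must be 'test' or 'paper', got {cfg.scale!r}")
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, stage: str, seeds: dict, inputs: list, status: dict) -> Path:
    manifest = {
        "stage": stage,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seeds": seeds,
        "input_hashes": {str(p): _sha256(Path(p)) for p in inputs},
        "status": status,
    }
    p = out_dir / f"manifest_{stage}.json"
    p.write_text(json.dumps(manifest, indent=2))
    return p


def run_generate(config: PipelineConfig, force: bool = False) -> Path:
    """Generate a synthetic cohort and write its CSV set plus the truth table."""
    out = Path(config.out_dir) / "cohort"
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    cohort = generate_cohort(
        DEFAULT_PROFILES,
        n_per_group=config.n_per_group,
        noise_cv=config.noise_cv,
        master_seed=config.master_seed,
        grid_step=config.grid_step,
    )
    paths = io.write_cohort(cohort.records, out)
    cohort.truth_frame().to_csv(out / "truth.csv", index=False)
    config.to_yaml(out / "config.yaml")
    write_manifest(
        out, "generate", {"master_seed": config.master_seed}, list(paths.values()),
        {s.record.meta.subject_id: "ok" for s in cohort.subjects},
    )
    return out


def subject_forcing(record: SubjectRecord):
    """Rebuild the model forcing from a subject's measured traces."""
    G = build_glucose_input(record.glucose_times, record.glucose_values,
                            record.meta.fasting_glucose)
    if record.iir_times.size >= 3:
        ciir = np.array(
            [convert_iir_to_cIIR(v, record.meta.sex) for v in record.iir_values]
        )
        f = fit_infusion_function(record.iir_times, ciir)
    else:
        from .units import ZERO_INFUSION

        f = ZERO_INFUSION
    return G, f


def run_fit(config: PipelineConfig, cohort_dir=None, resume: bool = True) -> Path:
    """Per-subject infusion fit, candidate-model fits, AIC selection, and the
    two outlier screens (RSS alone, then the 8-parameter vector; union
    flagged). Resumable: already-fitted subjects are skipped."""
    cohort_dir = Path(cohort_dir) if cohort_dir else Path(config.out_dir) / "cohort"
    out = Path(config.out_dir) / "fits"
    out.mkdir(parents=True, exist_ok=True)
    records = io.load_cohort(cohort_dir)
    means = cohort_means(records) if config.normalization == "cohort_means" else PAPER_MEANS
    est_cfg = config.estimation_config()

    fits_path = out / "fits.csv"
    done = set()
    rows = []
    if resume and fits_path.exists():
        prev = pd.read_csv(fits_path)
        rows = prev.to_dict("records")
        done = set(prev.subject_id)

    status = {}
    fits_by_subject: dict[str, dict[str, FitResult]] = {}
    groups = {}
    new_fits = False
    for rec in records:
        sid = rec.meta.subject_id
        groups[sid] = rec.meta.group
        if sid in done:
            status[sid] = "cached"
            continue
        try:
            G, f = subject_forcing(rec)
            fits = selection.fit_candidates(rec, G, f, est_cfg, models=list(config.models),
                                            means=means)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            status[sid] = f"failed: {exc!r}"
            continue
        fits_by_subject[sid] = fits
        best = fits.get("model_vi", next(iter(fits.values())))
        row = {"subject_id": sid, "group": rec.meta.group}
        row.update(best.to_dict())
        row["aic"] = selection.aic(best.rss, best.n_points, 8)
        rows.append(row)
        status[sid] = "ok"
        new_fits = True

    fit_df = pd.DataFrame(rows)
    if new_fits or not fits_path.exists():
        fit_df.to_csv(fits_path, index=False)

    if fits_by_subject:
        sel = selection.run_selection(fits_by_subject, groups)
        sel.to_frame().to_csv(out / "selection.csv", index=False)

    # outlier screens on the Model VI fits
    if len(fit_df) >= 4:
        seed_rss, seed_par = config.master_seed + 101, config.master_seed + 102
        # RSS and parameters live on multiplicative scales; screen both in log10
        ao_rss = adjusted_outlyingness(
            np.log10(np.maximum(fit_df[["rss"]].to_numpy(), 1e-300)), seed=seed_rss
        )
        rep_rss = flag_outliers(ao_rss)
        flagged = set(rep_rss.flagged)
        # the 8-D projection screen is ill-posed when every point is a hull
        # vertex (n <= d + 1): run it only on cohorts large enough to carry it
        if len(fit_df) > len(PARAM_NAMES) + 1:
            ao_par = adjusted_outlyingness(
                np.log10(fit_df[list(PARAM_NAMES)].to_numpy()), seed=seed_par
            )
            rep_par = flag_outliers(ao_par)
            flagged |= set(rep_par.flagged)
            cutoff_par = rep_par.cutoff
        else:
            ao_par = np.full(len(fit_df), np.nan)
            cutoff_par = np.nan
        pd.DataFrame(
            {
                "subject_id": fit_df.subject_id,
                "ao_rss": ao_rss,
                "cutoff_rss": rep_rss.cutoff,
                "ao_params": ao_par,
                "cutoff_params": cutoff_par,
                "flagged": [i in flagged for i in range(len(fit_df))],
            }
        ).to_csv(out / "outliers.csv", index=False)

    write_manifest(
        out, "fit", {"master_seed": config.master_seed},
        [cohort_dir / "metadata.csv", cohort_dir / "timeseries.csv"], status,
    )
    return out


def _clinical_indices_row(rec: SubjectRecord) -> dict:
    """AUC_IRI10, ISI, MCR and clamp DI from one subject's measured series."""
    to_iri = lambda pM: convert_units(pM, "insulin_uUml_to_pM", inverse=True)
    fasting_iri = to_iri(rec.meta.fasting_insulin)
    t10 = np.concatenate([[0.0], rec.sample_times[rec.sample_times <= 10.0]])
    iri10 = np.concatenate([[fasting_iri], to_iri(rec.insulin[rec.sample_times <= 10.0])])
    auc = auc_iri10(t10, iri10, fasting_iri)
    end_iri = to_iri(rec.insulin[-1])
    end_glu = convert_units(
        float(rec.glucose_values[-1]), "glucose_mgdl_to_mM", inverse=True
    )
    final30 = rec.gir_times >= 190.0
    gir30 = float(rec.gir_values[final30].mean()) if final30.any() else np.nan
    row = {"subject_id": rec.meta.subject_id, "group": rec.meta.group, "auc_iri10": auc}
    try:
        isi_v = isi(gir30, end_glu, end_iri)
    except (ValueError, ZeroDivisionError):
        isi_v = np.nan
    row["isi"] = isi_v
    try:
        row["mcr"] = mcr(rec.meta.weight, rec.meta.height, end_iri, fasting_iri)
    except ValueError:
        row["mcr"] = np.nan
    row["clamp_di"] = clamp_di(auc, isi_v) if np.isfinite(isi_v) else np.nan
    pk = peak_indices(t10_full := np.concatenate([[0.0], rec.sample_times]),
                      np.concatenate([[rec.meta.fasting_insulin], rec.insulin]))
    row.update(ipeak_clinical=pk.ipeak, itpi_clinical=pk.iTPI, peak_defined=pk.defined)
    return row


def run_analyze(config: PipelineConfig, cohort_dir=None, fits_dir=None) -> Path:
    """Indices, sensitivity table, parameter sweeps, group comparisons and
    parameter-index correlations from the fitted cohort."""
    cohort_dir = Path(cohort_dir) if cohort_dir else Path(config.out_dir) / "cohort"
    fits_dir = Path(fits_dir) if fits_dir else Path(config.out_dir) / "fits"
    out = Path(config.out_dir) / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    records = io.load_cohort(cohort_dir)
    fits_path = fits_dir / "fits.csv"
    if not fits_path.exists():
        raise FileNotFoundError(f"no fit table at {fits_path}; run the fit stage first")
    fits = pd.read_csv(fits_path)
    if fits.empty:
        raise ValueError("fit table is empty; nothing to analyze")
    missing = [r.meta.subject_id for r in records if r.meta.subject_id not in set(fits.subject_id)]
    by_id = {r.meta.subject_id: r for r in records}

    outliers_path = fits_dir / "outliers.csv"
    if outliers_path.exists():
        flags = pd.read_csv(outliers_path)
        keep = set(flags.loc[~flags.flagged, "subject_id"])
        fits = fits[fits.subject_id.isin(keep)]
        if fits.empty:
            raise ValueError("all subjects were flagged as outliers; nothing to analyze")

    # clinical + model indices
    idx_rows = [_clinical_indices_row(by_id[sid]) for sid in fits.subject_id]
    idx_df = pd.DataFrame(idx_rows)
    idx_df.to_csv(out / "indices.csv", index=False)

    # sensitivity on the fitted parameters
    subjects = []
    for _, row in fits.iterrows():
        rec = by_id[row.subject_id]
        params = ModelParameters(
            **{n: row[n] for n in PARAM_NAMES},
            I_b=rec.meta.fasting_insulin, CP_b=rec.meta.fasting_cpeptide,
        )
        G, _ = subject_forcing(rec)
        subjects.append((row.subject_id, params, G))
    sens = cohort_sensitivity(subjects, grid_step=config.grid_step)
    for target, tbl in sens.tables.items():
        tbl.to_csv(out / f"sensitivity_{target}.csv", index=False)
    sens.per_subject.to_csv(out / "sensitivity_per_subject.csv", index=False)

    # sweeps for the first subject
    sid0, params0, G0 = subjects[0]
    sweep_rows = []
    for which in ("k_ratio", "k_Iout", "both"):
        sw = parameter_sweep(params0, G0, which=which, grid_step=config.grid_step)
        for fac, pk, tp in zip(sw.factors, sw.ipeak, sw.iTPI):
            sweep_rows.append(
                {"subject_id": sid0, "which": which, "factor": fac, "ipeak": pk, "iTPI": tp}
            )
    pd.DataFrame(sweep_rows).to_csv(out / "sweeps.csv", index=False)

    # group stats on fitted parameters and correlations with clinical indices
    merged = fits.merge(idx_df, on=["subject_id", "group"])
    comparisons = stats.compare_groups(merged, list(PARAM_NAMES))
    comparisons.to_csv(out / "group_comparisons.csv", index=False)
    merged["k_ratio_x_k_Iout"] = merged.k_ratio * merged.k_Iout
    corr = stats.correlate(
        merged.dropna(subset=["isi", "mcr"]),
        [("k_Iout", "isi"), ("k_Iout", "mcr"), ("k_ratio", "auc_iri10"),
         ("k_ratio_x_k_Iout", "clamp_di")],
    )
    corr.to_csv(out / "correlations.csv", index=False)

    write_manifest(
        out, "analyze", {"master_seed": config.master_seed}, [fits_path],
        {"n_subjects": str(len(fits)), "missing_fits": ",".join(missing) or "none"},
    )
    return out
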