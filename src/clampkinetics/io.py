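"""CSV file contracts for cohort data (UTF-8, header row, '.' decimal)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import SubjectMeta, SubjectRecord

META_COLUMNS = [
    "subject_id",
    "sex",
    "weight_kg",
    "height_cm",
    "group",
    "fasting_glucose",
    "fasting_insulin",
    "fasting_cpeptide",
]


def write_cohort(records: list[SubjectRecord], out_dir) -> dict:
    """Write metadata/timeseries/glucose/infusion/GIR CSVs; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_rows, ts_rows, glu_rows, iir_rows, gir_rows = [], [], [], [], []
    for r in records:
        m = r.meta
        meta_rows.append(
            {
                "subject_id": m.subject_id,
                "sex": m.sex,
                "weight_kg": m.weight,
                "height_cm": m.height,
                "group": m.group,
                "fasting_glucose": m.fasting_glucose,
                "fasting_insulin": m.fasting_insulin,
                "fasting_cpeptide": m.fasting_cpeptide,
            }
        )
        for t, i, c in zip(r.sample_times, r.insulin, r.cpeptide):
            ts_rows.append(
                {"subject_id": m.subject_id, "time_min": t, "insulin_pM": i, "cpeptide_pM": c}
            )
        for t, g in zip(r.glucose_times, r.glucose_values):
            glu_rows.append({"subject_id": m.subject_id, "time_min": t, "glucose_mM": g})
        for t, v in zip(r.iir_times, r.iir_values):
            iir_rows.append({"subject_id": m.subject_id, "time_min": t, "iir_mU_kg_min": v})
        for t, v in zip(r.gir_times, r.gir_values):
            gir_rows.append({"subject_id": m.subject_id, "time_min": t, "gir_mg_kg_min": v})
    paths = {}
    for name, rows in [
        ("metadata", meta_rows),
        ("timeseries", ts_rows),
        ("glucose", glu_rows),
        ("infusion", iir_rows),
        ("gir", gir_rows),
    ]:
        p = out / f"{name}.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths[name] = p
    return paths


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def load_cohort(in_dir) -> list[SubjectRecord]:
    """Read the cohort CSV set written by :func:`write_cohort`."""
    d = Path(in_dir)
    meta = pd.read_csv(d / "metadata.csv")
    _require_columns(meta, META_COLUMNS, d / "metadata.csv")
    ts = pd.read_csv(d / "timeseries.csv")
    _require_columns(ts, ["subject_id", "time_min", "insulin_pM", "cpeptide_pM"],
                     d / "timeseries.csv")
    glu = pd.read_csv(d / "glucose.csv")
    _require_columns(glu, ["subject_id", "time_min", "glucose_mM"], d / "glucose.csv")
    iir = pd.read_csv(d / "infusion.csv") if (d / "infusion.csv").exists() else None
    gir = pd.read_csv(d / "gir.csv") if (d / "gir.csv").exists() else None

    records = []
    for _, row in meta.iterrows():
        sid = row["subject_id"]
        sub_ts = ts[ts.subject_id == sid].sort_values("time_min")
        sub_glu = glu[glu.subject_id == sid].sort_values("time_min")
        kw: dict = {}
        if iir is not None:
            sub = iir[iir.subject_id == sid].sort_values("time_min")
            kw["iir_times"] = sub["time_min"].to_numpy()
            kw["iir_values"] = sub["iir_mU_kg_min"].to_numpy()
        if gir is not None:
            sub = gir[gir.subject_id == sid].sort_values("time_min")
            kw["gir_times"] = sub["time_min"].to_numpy()
            kw["gir_values"] = sub["gir_mg_kg_min"].to_numpy()
        records.append(
            SubjectRecord(
                meta=SubjectMeta(
                    subject_id=str(sid),
                    sex=row["sex"],
                    weight=float(row["weight_kg"]),
                    height=float(row["height_cm"]),
                    group=row["group"],
                    fasting_glucose=float(row["fasting_glucose"]),
                    fasting_insulin=float(row["fasting_insulin"]),
                    fasting_cpeptide=float(row["fasting_cpeptide"]),
                ),
                sample_times=sub_ts["time_min"].to_numpy(),
                insulin=sub_ts["insulin_pM"].to_numpy(),
                cpeptide=sub_ts["cpeptide_pM"].to_numpy(),
                glucose_times=sub_glu["time_min"].to_numpy(),
                glucose_values=sub_glu["glucose_mM"].to_numpy(),
                **kw,
            )
        )
    return records
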