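"""AIC computation and per-subject model selection.

The candidate registry carries the full four-variable model plus two reduced
stand-in variants used to exercise the selection machinery (the original
study's alternative model structures are not part of this package):

* ``model_vi`` — all 8 parameters free.
* ``fixed_extraction`` — no hepatic extraction (k_ratio pinned at 1), K=7.
* ``no_provision`` — provision dynamics removed (alpha and beta pinned at the
  lower bound, so Y stays at 0 and the stored pool only depletes), K=6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import SubjectRecord
from .estimation import (
    EstimationConfig,
    FitResult,
    NormalizationMeans,
    ParamRestriction,
    fit_subject,
)
from .units import GlucoseInput, InfusionFunction


def aic(rss: float, n_points: int, n_params: int) -> float:
    """Akaike information criterion n*ln(2*pi*RSS/n) + n + 2K for a Gaussian
    residual model with the variance profiled out."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if n_params < 0:
        raise ValueError("n_params must be >= 0")
    if rss < 0:
        raise ValueError("rss must be nonnegative")
    if rss == 0:
        warnings.warn("AIC undefined at RSS=0; returning -inf", RuntimeWarning, stacklevel=2)
        return -np.inf
    n = n_points
    return float(n * np.log(2.0 * np.pi * rss / n) + n + 2 * n_params)


@dataclass(frozen=True)
class CandidateModel:
    """A candidate structure: name, parameter restriction and K."""

    name: str
    restriction: ParamRestriction

    @property
    def n_params(self) -> int:
        return self.restriction.n_free


MODEL_REGISTRY: dict[str, CandidateModel] = {
    "model_vi": CandidateModel("model_vi", ParamRestriction.full()),
    "fixed_extraction": CandidateModel(
        "fixed_extraction", ParamRestriction.fixing(k_ratio=1.0)
    ),
    "no_provision": CandidateModel(
        "no_provision", ParamRestriction.fixing(alpha=1e-6, beta=1e-6)
    ),
}


def fit_candidates(
    record: SubjectRecord,
    G: GlucoseInput,
    f: InfusionFunction,
    config: EstimationConfig,
    models: list[str] | None = None,
    means: NormalizationMeans | None = None,
) -> dict[str, FitResult]:
    """Fit each registered candidate to one subject."""
    names = list(models) if models is not None else list(MODEL_REGISTRY)
    out = {}
    for name in names:
        cand = MODEL_REGISTRY[name]
        out[name] = fit_subject(record, G, f, config, means=means,
                                restriction=cand.restriction)
    return out


def select_model(aic_by_model: dict[str, float]) -> str:
    """Argmin-AIC candidate; ties prefer fewer parameters, then registration
    order."""
    if not aic_by_model:
        raise ValueError("need at least one fitted candidate")
    reg_order = {name: i for i, name in enumerate(MODEL_REGISTRY)}
    return min(
        aic_by_model,
        key=lambda name: (
            aic_by_model[name],
            MODEL_REGISTRY[name].n_params if name in MODEL_REGISTRY else np.inf,
            reg_order.get(name, np.inf),
        ),
    )


@dataclass
class SelectionResult:
    """Per-subject best model and the AIC table behind it."""

    per_subject: list = field(default_factory=list)  # (subject_id, group, best, {model: aic})

    @property
    def counts(self) -> dict:
        """Best-model counts per glycemic group (rows sum to cohort size)."""
        out: dict[str, dict[str, int]] = {}
        for _, group, best, _ in self.per_subject:
            out.setdefault(best, {}).setdefault(group, 0)
            out[best][group] += 1
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        for sid, group, best, aics in self.per_subject:
            row = {"subject_id": sid, "group": group, "best_model": best}
            row.update({f"aic_{k}": v for k, v in aics.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def run_selection(
    fits_by_subject: dict[str, dict[str, FitResult]],
    groups: dict[str, str],
    n_points: int = 18,
) -> SelectionResult:
    """Build the selection table from per-subject candidate fits."""
    result = SelectionResult()
    for sid, fits in fits_by_subject.items():
        aics = {
            name: aic(fr.rss, n_points, MODEL_REGISTRY[name].n_params)
            for name, fr in fits.items()
        }
        result.per_subject.append((sid, groups.get(sid, "NA"), select_model(aics), aics))
    return result
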