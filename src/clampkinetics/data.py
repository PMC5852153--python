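"""Core data containers for one subject's clamp study."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Serum sampling times (min) for insulin and C-peptide during the consecutive
#: hyperglycemic (0-90 min) and hyperinsulinemic-euglycemic (100-220 min) clamps.
SAMPLING_TIMES = np.array([5.0, 10.0, 15.0, 60.0, 75.0, 90.0, 100.0, 190.0, 220.0])

GROUPS = ("NGT", "borderline", "T2DM")


@dataclass(frozen=True)
class SubjectMeta:
    """Subject metadata and fasting (basal) values.

    fasting_glucose is in mM; fasting_insulin (I_b) and fasting_cpeptide (CP_b)
    are in pM and enter the model as initial conditions.
    """

    subject_id: str
    sex: str
    weight: float
    height: float
    group: str
    fasting_glucose: float
    fasting_insulin: float
    fasting_cpeptide: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be strictly positive")
        for name in ("fasting_glucose", "fasting_insulin", "fasting_cpeptide"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass
class SubjectRecord:
    """Measured clamp series for one subject.

    glucose_times/glucose_values are the 5-min-average plasma glucose readings;
    sample_times carries the serum sampling grid with insulin/cpeptide in pM.
    iir is the insulin infusion rate (mU/kg/min) and gir the glucose infusion
    rate (mg/kg/min), each on its own time grid.
    """

    meta: SubjectMeta
    sample_times: np.ndarray
    insulin: np.ndarray
    cpeptide: np.ndarray
    glucose_times: np.ndarray
    glucose_values: np.ndarray
    iir_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    iir_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    gir_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    gir_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        for name in (
            "sample_times",
            "insulin",
            "cpeptide",
            "glucose_times",
            "glucose_values",
            "iir_times",
            "iir_values",
            "gir_times",
            "gir_values",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.sample_times.size == self.insulin.size == self.cpeptide.size):
            raise ValueError("sample_times, insulin and cpeptide must have equal length")
        if self.glucose_times.size != self.glucose_values.size:
            raise ValueError("glucose_times and glucose_values must have equal length")
        # estimation is invariant to the on-disk ordering of sampling rows
        order = np.argsort(self.sample_times)
        self.sample_times = self.sample_times[order]
        self.insulin = self.insulin[order]
        self.cpeptide = self.cpeptide[order]
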