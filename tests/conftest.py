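import numpy as np
import pytest

from clampkinetics.estimation import cohort_means
from clampkinetics.model import ModelParameters
from clampkinetics.synthetic import generate_cohort
from clampkinetics.units import GlucoseInput, build_glucose_input


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Six noiseless synthetic subjects (two per glycemic group)."""
    return generate_cohort(n_per_group=2, noise_cv=0.0, master_seed=7)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Twelve subjects with the default 5% observation noise."""
    return generate_cohort(n_per_group=4, noise_cv=0.05, master_seed=1)


@pytest.fixture(scope="session")
def noisy_means(noisy_cohort):
    return cohort_means(noisy_cohort.records)


@pytest.fixture
def canonical_params():
    """A mid-range normal-tolerance parameter set."""
    return ModelParameters(
        alpha=0.05, beta=15.0, h=5.0, m=0.2, X_b=2000.0,
        k_ratio=0.55, k_Iout=0.2, k_CPout=0.05, I_b=40.0, CP_b=400.0,
    )


@pytest.fixture
def clamp_glucose():
    """A clean two-plateau clamp glucose input (fasting 5 mM, plateau 11.1)."""
    times = np.arange(5.0, 220.0 + 1e-9, 5.0)
    vals = np.where(times <= 90, 11.1, np.where(times <= 130, 7.0, 5.0))
    return build_glucose_input(times, vals, fasting_glucose=5.0)


@pytest.fixture
def basal_glucose():
    """Glucose pinned at fasting — never crosses any plausible threshold."""
    return GlucoseInput(breakpoints=np.array([0.0]), values=np.array([5.0]),
                        pre_window_value=5.0)
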