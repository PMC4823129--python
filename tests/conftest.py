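import numpy as np
import pandas as pd
import pytest

from lnmrisk import run_recovery_study

#: worked weight-derivation example: multivariate Wald chi-squares of the
#: five score factors as printed in the published model, and the one-decimal
#: weights they imply after division by the minimum (4.496)
REFERENCE_CHI2 = {
    "vascular_invasion": 11.665,
    "bclc_b_c": 5.632,
    "mir145_positive": 6.011,
    "mir31_positive": 7.485,
    "mir92a_positive": 4.496,
}
REFERENCE_WEIGHTS = {
    "vascular_invasion": 2.6,
    "bclc_b_c": 1.3,
    "mir145_positive": 1.3,
    "mir31_positive": 1.7,
    "mir92a_positive": 1.0,
}


def make_cohort(times, events, **factor_columns) -> pd.DataFrame:
    """Small hand-built patient table."""
    n = len(times)
    data = {"patient_id": [f"P{i + 1:03d}" for i in range(n)]}
    for name, values in factor_columns.items():
        assert len(values) == n
        data[name] = list(values)
    data["time_months"] = list(times)
    data["event"] = list(events)
    data["cohort"] = "training"
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def recovery_study() -> dict:
    """End-to-end parameter-recovery study shared across test modules.

    50 replicates of a 2000-patient cohort drawn under the default
    (reference) hazard ratios; each replicate re-runs screening, the joint
    fit, weight derivation, and cutoff selection.
    """
    return run_recovery_study(n=2000, replicates=50, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
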