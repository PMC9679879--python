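import numpy as np
import pandas as pd
import pytest

from mammoeval import SimulationConfig, add_outcome_groups, simulate_study

#: Outcome-group sizes of the full reference cohort (printed counts).
FULL_COUNTS = {"TP": 597, "FN": 126, "FP": 8432, "TN": 112_598}
#: Outcome-group sizes of the oversampled analysis subset.
SUBSET_COUNTS = {"TP": 465, "FN": 111, "FP": 3474, "TN": 33_267}


@pytest.fixture(scope="session")
def study_full_counts():
    return dict(FULL_COUNTS)


@pytest.fixture(scope="session")
def study_subset_counts():
    return dict(SUBSET_COUNTS)


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic study shared across tests: exam table + score panel."""
    exams, panel = simulate_study(SimulationConfig(n_women=2500), seed=123)
    return add_outcome_groups(exams), panel


@pytest.fixture(scope="session")
def large_study():
    """A default-configuration cohort large enough for marginal checks."""
    config = SimulationConfig(n_women=35_000)
    exams, panel = simulate_study(config, seed=2024)
    return config, add_outcome_groups(exams), panel


def confusion_from_counts(counts: dict, weights: dict | None = None):
    """Expand group counts into aligned call/outcome/weight arrays."""
    call, cancer, w = [], [], []
    for g, n in counts.items():
        call += [g in ("TP", "FP")] * n
        cancer += [g in ("TP", "FN")] * n
        w += [1.0 if weights is None else weights[g]] * n
    return (
        np.array(call, dtype=bool),
        np.array(cancer, dtype=bool),
        np.array(w, dtype=float),
    )
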