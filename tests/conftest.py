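import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mlas

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_registry() -> mlas.Registry:
    """Three hand-built patients: a death, a transplant, a censoring, with a
    time-varying severity update for the first patient."""
    data = pd.DataFrame(
        {
            "patient_id": ["A", "B", "C"],
            "list_day": [0, 5, 10],
            "age": [60.0, 45.0, 52.0],
            "severity": [1.0, 0.2, 0.5],
            "outcome": ["death", "transplant", "censor"],
            "outcome_day": [3, 4, 6],
            "post_outcome": [np.nan, "death", np.nan],
            "post_outcome_day": [np.nan, 100.0, np.nan],
        }
    )
    tv = pd.DataFrame(
        {"patient_id": ["A"], "day": [1], "name": ["severity"], "value": [2.5]}
    )
    return mlas.Registry(data, tv)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest strong-selection cohort shared by integration tests."""
    cfg = mlas.preset("strong_selection", n=400, seed=42)
    return mlas.simulate(cfg)


@pytest.fixture(scope="session")
def selection_study() -> pd.DataFrame:
    """The replicated strong-selection simulation study (slow; shared)."""
    from mlas.study import run_selection_study

    return run_selection_study(
        preset_name="strong_selection", n=5000, replicates=20, seed=0
    )
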