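import numpy as np
import pandas as pd
import pytest

from sepsikit import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-patient mixed cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n_patients=120, septic_fraction=0.3, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_stays(los_list, **overrides):
    """Minimal stays table for hand-built fixtures."""
    n = len(los_list)
    base = {
        "stay_id": list(range(1, n + 1)),
        "patient_id": [100 + i for i in range(n)],
        "los_hours": los_list,
        "age": [60.0] * n,
        "sex": ["F"] * n,
        "care_unit": ["MICU"] * n,
        "elective_surgical": [False] * n,
        "pre_icu_antibiotics": [False] * n,
        "ever_ventilated": [False] * n,
        "hosp_to_icu_hours": [5.0] * n,
        "source_system": ["metavision"] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)
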