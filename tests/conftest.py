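import numpy as np
import pandas as pd
import pytest

from csfmetals import CohortConfig, CohortDataset, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> CohortDataset:
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def clean_cohort() -> CohortDataset:
    """No missingness, full plasma coverage: convenient for exact checks."""
    return generate_cohort(CohortConfig(missingness={}, plasma_subset_n=193, seed=5))


from csfmetals.scenarios import null_config as make_null_config  # noqa: F401
from csfmetals.scenarios import planted_config as make_planted_config  # noqa: F401


@pytest.fixture()
def toy_two_view() -> CohortDataset:
    """Six patients, two tiny numeric views plus diagnosis."""
    frame = pd.DataFrame(
        {
            "diagnosis": ["AD", "AD", "MCI", "MCI", "HC", "HC"],
            "A": [1.0, 2.0, 3.0, 4.0, np.nan, 6.0],
            "B": [0.0, 5.0, 2.0, 7.0, 1.0, 3.0],
            "X": [1.0, 1.0, 0.0, 1.0, 0.0, np.nan],
            "Y": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
        },
        index=pd.Index([f"P{i}" for i in range(1, 7)], name="patient_id"),
    )
    return CohortDataset(
        frame,
        view_columns={"clinical": ["diagnosis"], "v1": ["A", "B"], "v2": ["X", "Y"]},
        categorical_levels={"diagnosis": ["AD", "MCI", "HC"]},
    )
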