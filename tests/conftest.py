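import numpy as np
import pandas as pd
import pytest

from suscept.schema import CohortTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort_frame(n=6, seed=0):
    """Small, fully valid scale-level cohort frame."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "department": (["ICU", "emergency", "other"] * n)[:n],
            "shift_pattern": (["three_shift_8h", "two_shift_12h"] * n)[:n],
            "tenure_years": np.round(rng.uniform(1, 20, n), 1),
            "job_control": np.round(rng.uniform(30, 90, n), 1),
            "psych_demands": np.round(rng.uniform(15, 45, n), 1),
            "supervisor_support": np.round(rng.uniform(5, 16, n), 1),
            "coworker_support": np.round(rng.uniform(5, 16, n), 1),
            "hcc_raw": np.round(rng.lognormal(1.2, 0.7, n), 3),
            "ee": np.round(rng.uniform(1, 7, n), 2),
            "dp": np.round(rng.uniform(1, 7, n), 2),
            "pe": np.round(rng.uniform(1, 7, n), 2),
        }
    )


@pytest.fixture
def cohort_frame():
    return make_cohort_frame()


@pytest.fixture
def cohort_table(cohort_frame):
    return CohortTable(cohort_frame, "fixture").validate()


@pytest.fixture
def cohort_csv(tmp_path, cohort_frame):
    path = tmp_path / "cohort.csv"
    cohort_frame.to_csv(path, index=False)
    return path
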