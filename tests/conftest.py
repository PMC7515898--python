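import numpy as np
import pandas as pd
import pytest

from pyroage import (
    CohortTable,
    default_cohort_config,
    generate_cohort,
    random_split,
)


def make_frame(rows):
    """Rows: (sample_id, age, study, 7 cpg values [None = missing])."""
    data = []
    for sid, age, study, meth in rows:
        row = {"sample_id": sid, "age": age, "study": study}
        for i, v in enumerate(meth, start=1):
            row[f"cpg{i}"] = np.nan if v is None else v
        data.append(row)
    return pd.DataFrame(data)


@pytest.fixture
def tiny_frame():
    return make_frame(
        [
            ("s1", 25.0, "study_a", [10, 12, 14, 16, 18, 20, 22]),
            ("s2", 50.0, "study_a", [30, 32, 34, 36, 38, 40, 42]),
            ("s3", 75.0, "study_b", [50, 52, 54, 56, 58, 60, 62]),
        ]
    )


@pytest.fixture
def tiny_table(tiny_frame):
    return CohortTable(tiny_frame)


@pytest.fixture(scope="session")
def cohort300():
    return generate_cohort(default_cohort_config(n_samples=300, seed=42))


@pytest.fixture(scope="session")
def split300(cohort300):
    return random_split(cohort300, 200, seed=7)
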