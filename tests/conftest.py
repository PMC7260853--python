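import numpy as np
import pytest

from cordmap.geometry import normalize_table
from cordmap.synthetic import CohortConfig, generate_cohort

# frozen fixture for the Hotelling oracle-equivalence check; expected
# values were computed once with tests/oracles.py and frozen below
HOTELLING_FIXTURE = {
    "x1": [(0.42, 0.61), (0.35, 0.70), (0.50, 0.55), (0.44, 0.66), (0.39, 0.58)],
    "x2": [(0.48, 0.49), (0.55, 0.47), (0.52, 0.60), (0.60, 0.52), (0.46, 0.44)],
    "t2": 14.926516151441472,
    "f_stat": 6.530350816255644,
    "df1": 2,
    "df2": 7,
    "p_value": 0.025097572931541166,
}


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort_norm(small_cohort):
    return normalize_table(small_cohort.cells)
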