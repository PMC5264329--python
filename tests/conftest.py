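import numpy as np
import pytest

from cervecon import (
    CaseMix,
    DalyParams,
    LifeTable,
    TransitionMatrix,
    UnitCostSchedule,
)
from cervecon.profiles import (
    load_life_table,
    load_screening_table,
    load_transition_matrix,
)

#: the study's printed annual transition matrix (rows: UNTESTED,
#: HPV_INFECTION, CIN1, CIN2, CIN3, CANCER, DEAD)
STUDY_MATRIX = np.array(
    [
        [0.876, 0.123, 0.000, 0.000, 0.000, 0.000, 0.001],
        [0.300, 0.599, 0.086, 0.014, 0.000, 0.000, 0.001],
        [0.135, 0.015, 0.685, 0.149, 0.015, 0.000, 0.001],
        [0.120, 0.030, 0.140, 0.659, 0.050, 0.000, 0.001],
        [0.000, 0.000, 0.014, 0.026, 0.919, 0.040, 0.001],
        [0.000, 0.000, 0.000, 0.000, 0.000, 0.761, 0.239],
        [0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 1.000],
    ]
)

ARM_CASE_MIXES = {
    "VIA_VILI": {"CIN1": 8, "CIN2": 3, "CIN3": 3},
    "TCT": {"CIN1": 2, "CIN3": 1},
    "HPV": {"CIN1": 2, "CIN2": 1, "CIN3": 3, "CANCER": 1},
}


@pytest.fixture(scope="session")
def study_matrix() -> TransitionMatrix:
    return TransitionMatrix.from_array(STUDY_MATRIX)


@pytest.fixture(scope="session")
def bundled_matrix() -> TransitionMatrix:
    return load_transition_matrix()


@pytest.fixture(scope="session")
def schedule() -> UnitCostSchedule:
    return UnitCostSchedule()


@pytest.fixture(scope="session")
def daly_params() -> DalyParams:
    return DalyParams()


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return load_life_table()


@pytest.fixture(scope="session")
def screening_components():
    return load_screening_table()


@pytest.fixture(scope="session")
def case_mixes() -> dict[str, CaseMix]:
    return {arm: CaseMix(mix) for arm, mix in ARM_CASE_MIXES.items()}
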