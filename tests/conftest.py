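import numpy as np
import pandas as pd
import pytest

from prelsc.expression import StageExpressionMatrix
from prelsc.lda import DilutionCohort


@pytest.fixture
def single_dose_cohort() -> DilutionCohort:
    """One dose of 10^4 cells, 4 of 7 recipients engrafted."""
    return DilutionCohort("toy", (1e4,), (7,), (4,))


@pytest.fixture
def multi_dose_cohort() -> DilutionCohort:
    """Three doses, increasing positive fraction with dose."""
    return DilutionCohort("toy", (100.0, 1000.0, 10000.0), (7, 7, 7), (1, 5, 7))


@pytest.fixture
def toy_stage_matrix() -> StageExpressionMatrix:
    """Four genes, four stages; one rising, one flat, one falling, one mixed."""
    stages = ("ETP", "DN2", "DN3a", "DP")
    values = pd.DataFrame(
        {
            "ETP": [10.0, 100.0, 80.0, 10.0],
            "DN2": [14.0, 100.0, 40.0, 13.0],
            "DN3a": [28.0, 100.0, 20.0, 16.9],
            "DP": [28.0, 100.0, 10.0, 5.0],
        },
        index=["rising", "flat", "falling", "mixed"],
    )
    return StageExpressionMatrix(values, stages)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
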