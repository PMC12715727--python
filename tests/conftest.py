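import numpy as np
import pandas as pd
import pytest

from behavnet.synthetic import IsingParameters, enumerate_joint_pmf

BLOCK_A = [2, 3, 4]  # salty, smoking, drinking
BLOCK_B = [0, 1, 5, 6]  # fruit, vegetable, exercise, sleep


def two_block_weights(p=7, w_a=1.0, w_b=1.0):
    W = np.zeros((p, p))
    for block, w in ((BLOCK_A, w_a), (BLOCK_B, w_b)):
        for a in range(len(block)):
            for b in range(a + 1, len(block)):
                W[block[a], block[b]] = W[block[b], block[a]] = w
    return W


@pytest.fixture(scope="session")
def uniform_pmf7():
    return enumerate_joint_pmf(IsingParameters(tau=np.zeros(7), W=np.zeros((7, 7))))


@pytest.fixture(scope="session")
def two_block_pmf():
    params = IsingParameters(tau=np.full(7, -1.5), W=two_block_weights())
    return enumerate_joint_pmf(params)


def make_record(**overrides):
    """One complete, healthy survey record; override fields per test."""
    base = {
        "record_id": 0,
        "gender": "female",
        "age": 80,
        "residence": "city",
        "education_years": 6,
        "co_residence": "household",
        "economic_status": "so_so",
        "sleep_hours": 8,
        "fruit_freq": "A",
        "veg_freq": "A",
        "flavor": "bland",
        "smoking_now": "no",
        "drinking_now": "no",
        "regular_exercise": "yes",
        "qol_rating": "B",
        "health_rating": "B",
    }
    base.update(overrides)
    return base


def make_table(*records):
    return pd.DataFrame([make_record(record_id=i, **r) for i, r in enumerate(records)])


@pytest.fixture
def survey_row_factory():
    return make_record


@pytest.fixture
def survey_table_factory():
    return make_table
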