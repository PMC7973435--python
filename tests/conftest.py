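import numpy as np
import pandas as pd
import pytest

import lexirt as lx


@pytest.fixture(scope="session")
def small_calibration():
    """40 Rasch-conforming items x 200 persons with known truth."""
    bank = lx.generate_item_bank(
        20, 20, seed=1, discrimination_dist={"kind": "constant", "value": 1.0})
    cohort = lx.generate_cohort(200, seed=1)
    responses = lx.simulate_session(bank, cohort, seed=1)
    return bank, cohort, responses


@pytest.fixture(scope="session")
def small_rasch_fit(small_calibration):
    bank, cohort, responses = small_calibration
    model = lx.fit_model(responses, model_kind="rasch_g")
    abilities = lx.estimate_abilities(model, responses)
    return model, abilities


@pytest.fixture(scope="session")
def tiny_responses():
    """10 persons x 5 items — small enough for brute-force oracles."""
    bank = lx.generate_item_bank(3, 2, seed=5)
    cohort = lx.generate_cohort(10, seed=5)
    return lx.simulate_session(bank, cohort, seed=5)


def make_responses(correct_matrix, rt=1.0):
    """Long response table from a persons x items 0/1 array."""
    correct_matrix = np.asarray(correct_matrix)
    n, j = correct_matrix.shape
    rows = []
    for i in range(n):
        for k in range(j):
            rows.append({
                "person_id": f"s{i:02d}", "item_id": f"i{k:02d}",
                "block_index": 1, "trial_index": k + 1,
                "correct": int(correct_matrix[i, k]), "rt_seconds": rt,
            })
    return pd.DataFrame(rows)
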