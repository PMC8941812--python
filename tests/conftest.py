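import numpy as np
import pandas as pd
import pytest

from ceaphen import GeneratorParams, generate_dataset
from ceaphen.pipeline import prepare_tables


def make_claims(rows):
    """Build a claims DataFrame from (pid, date, icd9, fee, specialty, seq)."""
    return pd.DataFrame(
        rows, columns=["participant_id", "service_date", "icd9_raw",
                       "fee_item", "specialty", "adjudication_seq"]
    ).assign(service_date=lambda d: pd.to_datetime(d["service_date"]))


@pytest.fixture(scope="session")
def small_dataset():
    """A n=300 synthetic dataset with default generator parameters."""
    params = GeneratorParams(n_participants=300, seed=11)
    truth, participants, discharges, claims = generate_dataset(params)
    return params, truth, participants, discharges, claims


@pytest.fixture(scope="session")
def prepared(small_dataset):
    params, truth, participants, discharges, claims = small_dataset
    cohort, claims_prep = prepare_tables(
        truth, participants, discharges, claims, params.test_year)
    return params, truth, cohort, discharges, claims_prep
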