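import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mnartrial.data import TrialDataset
from mnartrial.simulate import SimulationParams, simulate_trial

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=30,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mar_trial():
    """MAR trial (missingness independent of scores): n=800, true effect 2."""
    params = SimulationParams(
        n_total=800,
        seed=101,
        r0_coefs={"const": 2.5},
        y1_coefs={"const": 40.0, "Y0": 6.0, "T": 2.0},
        r1_coefs={"const": 2.0, "T": -0.5},
    )
    return simulate_trial(params)


@pytest.fixture(scope="session")
def mar_dataset(mar_trial):
    return mar_trial[0]


@pytest.fixture()
def two_row_dataset():
    df = pd.DataFrame(
        {
            "participant_id": ["a", "b"],
            "centre": [1, 2],
            "arm": [1, 0],
            "y0": [38.0, 44.0],
            "y1": [41.0, np.nan],
            "z": [np.nan, np.nan],
        }
    )
    return TrialDataset(df)
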