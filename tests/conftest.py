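import numpy as np
import pandas as pd
import pytest

from demorates import SimulationConfig, generate_survey


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def survey_pair(default_config):
    """One default synthetic survey (IR-style women, BR-style births)."""
    return generate_survey(default_config, seed=20240)


@pytest.fixture()
def tiny_women():
    """Five hand-sized women records with explicit birth histories."""
    return pd.DataFrame(
        {
            "caseid": [1, 2, 3, 4, 5],
            "v005": [1_000_000] * 5,
            "v008": [1420, 1420, 1421, 1419, 1420],
            "v011": [1200, 1160, 1050, 980, 900],
            "v021": [1, 1, 2, 2, 3],
            "v022": [1, 1, 1, 2, 2],
            "b3_01": [1390.0, 1386.0, 1400.0, np.nan, 1100.0],
            "b3_02": [np.nan, 1412.0, np.nan, np.nan, np.nan],
            "b7_01": [np.nan, 2.0, np.nan, np.nan, 14.0],
            "b7_02": [np.nan, np.nan, np.nan, np.nan, np.nan],
        }
    )
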