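import numpy as np
import pandas as pd
import pytest

from dmintake.synthetic_data import LiteratureGenConfig, generate_literature


@pytest.fixture(scope="session")
def literature_df() -> pd.DataFrame:
    """One medium study-clustered literature dataset shared across tests."""
    return generate_literature(LiteratureGenConfig(n_studies=40, n_obs_total=170, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20200684)
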