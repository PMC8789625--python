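import numpy as np
import pandas as pd
import pytest

from womab import generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One seeded synthetic normative cohort (n=168) shared across tests."""
    return generate_cohort(seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
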