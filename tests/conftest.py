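import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from itraqpipe.io_formats import RatioMatrix, infer_groups, load_table1_fixture

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1() -> RatioMatrix:
    return load_table1_fixture()


def make_matrix(values: dict[str, list], proteins: list[str]) -> RatioMatrix:
    """Small RatioMatrix from {sample: column} with NaN for missing."""
    df = pd.DataFrame(values, index=proteins, dtype=float)
    return RatioMatrix(df, infer_groups(df.columns))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
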