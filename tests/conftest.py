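import numpy as np
import pandas as pd
import pytest

from aedes_ude.climate import ClimateSeries
from aedes_ude.vital_rates import VitalParams


@pytest.fixture(scope="session")
def default_params() -> VitalParams:
    return VitalParams.default()


@pytest.fixture()
def constant_climate():
    """One year of constant 25 degC, zero rain."""
    dates = pd.date_range("2020-01-01", periods=366, freq="D")
    return ClimateSeries("const", dates, np.full(366, 25.0), np.zeros(366))


@pytest.fixture(scope="session")
def small_benchmark():
    """The packaged 3-city x 2-year synthetic benchmark (regenerated in memory)."""
    from aedes_ude.synthetic import load_benchmark

    return load_benchmark("small")
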