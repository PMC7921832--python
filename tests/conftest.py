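import numpy as np
import pandas as pd
import pytest

from elaforecast import SyntheticSpec, TimeSeries, generate


@pytest.fixture()
def weekly_series():
    """Small deterministic weekly series (12 weeks)."""
    dates = pd.date_range("2018-01-02", periods=12, freq="7D")
    values = 10.0 + np.arange(12.0)
    return TimeSeries(dates, values, name="toy")


@pytest.fixture(scope="session")
def flu_series():
    """One default synthetic influenza-like series (n=221)."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
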