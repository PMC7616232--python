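import numpy as np
import pandas as pd
import pytest

from luxlog import EpochSeries, LightRecording

T0 = pd.Timestamp("2023-03-06 00:00:00")


def make_series(values, epoch="1min", start=T0, allow_negative=True) -> EpochSeries:
    """Build an EpochSeries from a plain value list (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    index = pd.date_range(start, periods=len(values), freq=pd.Timedelta(epoch))
    return EpochSeries(
        pd.Series(values, index=index),
        pd.Timedelta(epoch),
        allow_negative=allow_negative,
    )


def make_recording(values, epoch="1min", start=T0, name="rec", channel="White Light"):
    return LightRecording(name, {channel: make_series(values, epoch, start)})


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def recording_factory():
    return make_recording


@pytest.fixture
def rng():
    return np.random.default_rng(20230306)
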