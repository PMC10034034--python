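"""Shared fixtures: minute time bases and reference canopy curves."""

from datetime import date, datetime

import numpy as np
import pandas as pd
import pytest

from irrisched.canopy import INTEGRATION_MINUTES, ReferenceCurve

DAY = date(2021, 8, 9)


@pytest.fixture
def window_index():
    """One-minute timestamps over the 09:00-19:00 integration window."""
    return pd.date_range(datetime(2021, 8, 9, 9, 0),
                         periods=INTEGRATION_MINUTES, freq="1min")


@pytest.fixture
def flat_reference(window_index):
    """A constant 28 degC reference curve over the full window."""
    return ReferenceCurve(DAY, pd.Series(28.0, index=window_index))


def make_reference(window_index, values) -> ReferenceCurve:
    vals = np.broadcast_to(np.asarray(values, dtype=float), (len(window_index),))
    return ReferenceCurve(DAY, pd.Series(vals.copy(), index=window_index))
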