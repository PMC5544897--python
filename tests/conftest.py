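import datetime as dt

import numpy as np
import pandas as pd
import pytest

from idioplan import PatientConfig, SymptomTimeSeries
from idioplan.efa import FactorModel

# Published worked-example loading matrices (loadings below .10 omitted -> 0).
EXPLORATORY_LOADINGS = np.array(
    [
        [0.31, 0.40],
        [0.97, 0.00],
        [0.00, 0.58],
        [0.00, 0.57],
        [0.00, 0.65],
        [0.34, 0.40],
        [0.00, 0.43],
        [0.00, 0.49],
        [0.00, 0.56],
        [0.00, 0.00],
    ]
)

CONFIRMATORY_LOADINGS = np.array(
    [
        [0.569, 0.129],
        [0.810, 0.000],
        [0.000, 0.624],
        [0.000, 0.519],
        [0.000, 0.657],
        [0.626, 0.094],
        [0.000, 0.368],
        [0.000, 0.670],
        [0.000, 0.437],
    ]
)


@pytest.fixture
def two_item_config():
    return PatientConfig(
        patient_code="p01",
        items=[("item1", "felt anxious"), ("item2", "avoided situations")],
        scale_min=0,
        scale_max=8,
        schedule=[dt.time(8), dt.time(14), dt.time(20)],
    )


@pytest.fixture
def exploratory_model():
    """A FactorModel carrying the published exploratory pattern matrix."""
    lam = EXPLORATORY_LOADINGS
    return FactorModel(
        k=2,
        loadings=lam,
        phi=np.array([[1.0, 0.56], [0.56, 1.0]]),
        uniquenesses=np.clip(1 - np.sum(lam**2, axis=1), 0.05, 1.0),
        item_ids=[f"item{i + 1}" for i in range(10)],
    )


def make_series(values, scale_min=0.0, scale_max=8.0, item_ids=None):
    values = np.asarray(values, dtype=float)
    t, i = values.shape
    if item_ids is None:
        item_ids = [f"item{j + 1}" for j in range(i)]
    return SymptomTimeSeries(
        values=values,
        timestamps=pd.date_range("2024-01-01 08:00", periods=t, freq="8h"),
        item_ids=item_ids,
        item_texts=list(item_ids),
        scale_min=scale_min,
        scale_max=scale_max,
    )
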