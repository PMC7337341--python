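import numpy as np
import pandas as pd
import pytest

from hyperniche.occurrences import OccurrenceSet
from hyperniche.rasters import ClimateStack, GridSpec
from hyperniche.synthetic import SyntheticScenario, generate_climate, sample_occurrences


def make_occ(rows):
    """OccurrenceSet from (lon, lat, year) tuples."""
    df = pd.DataFrame(rows, columns=["lon", "lat", "year"])
    return OccurrenceSet(df)


@pytest.fixture(scope="session")
def scenario():
    """Small expanding-niche scenario reused across module tests."""
    return SyntheticScenario(nrows=60, ncols=120, seed=1)


@pytest.fixture(scope="session")
def stack(scenario):
    return generate_climate(scenario)


@pytest.fixture(scope="session")
def occurrences(scenario):
    return sample_occurrences(scenario)


@pytest.fixture()
def toy_stack():
    """4x4 two-layer stack with two nodata cells, 1-degree cells."""
    grid = GridSpec(4, 4, 0.0, 0.0, 1.0)
    a = np.arange(16, dtype=float).reshape(4, 4)
    b = np.arange(16, dtype=float).reshape(4, 4) * 10
    a[0, 0] = np.nan
    b[3, 3] = np.nan
    return ClimateStack(np.stack([a, b]), ["a", "b"], grid)
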