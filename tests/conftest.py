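import numpy as np
import pandas as pd
import pytest

from c3c4niche import synthetic_world as sw
from c3c4niche.rasters import EnvGrid, GridSpec, MonthlyStack


@pytest.fixture(scope="session")
def default_world():
    return sw.make_world(sw.WorldConfig(seed=11))


@pytest.fixture(scope="session")
def qc_bundle(default_world):
    """World + lineages + error-laden occurrence records at default rates."""
    lc = sw.LineageConfig(seed=11, occurrences_per_species=40)
    groups, truth = sw.simulate_lineages(lc, default_world)
    records = sw.simulate_occurrences(groups, truth, default_world, lc)
    return {"world": default_world, "config": lc, "groups": groups,
            "truth": truth, "records": records}


@pytest.fixture
def unit_spec():
    """10x10 one-degree grid, NW corner at (10N, 0E)."""
    return GridSpec(west=0.0, north=10.0, cell_size=1.0, nrows=10, ncols=10)


@pytest.fixture
def toy_matrix():
    """Small env matrix with two taxa and two variables plus a missing value."""
    return pd.DataFrame(
        {
            "taxon": ["a", "a", "a", "b", "b"],
            "latitude": [0.0, 1.0, 2.0, 3.0, 4.0],
            "longitude": [0.0, 1.0, 2.0, 3.0, 4.0],
            "MAT": [1.0, 2.0, 100.0, 10.0, 20.0],
            "MAP": [5.0, np.nan, 7.0, 8.0, 9.0],
        }
    )


def make_monthly(spec, values, variable="x"):
    """MonthlyStack with a constant per-month value over the whole grid."""
    layers = np.stack(
        [np.full((spec.nrows, spec.ncols), v, dtype=float) for v in values]
    )
    return MonthlyStack(spec, variable, layers)


@pytest.fixture
def hand_months(unit_spec):
    temps = make_monthly(
        unit_spec, [0, 2, 6, 12, 18, 24, 26, 24, 18, 12, 6, 2], "tmean"
    )
    precs = make_monthly(
        unit_spec, [10, 10, 10, 10, 10, 100, 100, 100, 10, 10, 10, 10], "prec"
    )
    return temps, precs
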