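import numpy as np
import pandas as pd
import pytest

from regioncoord.panel_io import default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture
def tiny_panel_long(scheme, tmp_path):
    """2 counties x 1 year x 20 indicators, long CSV on disk."""
    rng = np.random.Generator(np.random.PCG64(42))
    rows = []
    for county in ("Alpha", "Beta"):
        for ind in scheme.indicator_ids:
            rows.append((county, 2020, ind, float(rng.uniform(1, 100))))
    df = pd.DataFrame(rows, columns=["county", "year", "indicator", "value"])
    path = tmp_path / "panel_long.csv"
    df.to_csv(path, index=False)
    return path, df


def make_panel_df(n_counties=5, years=(2020,), seed=0, scheme=None):
    """In-memory long-form panel frame with positive random values."""
    scheme = scheme or default_scheme()
    rng = np.random.Generator(np.random.PCG64(seed))
    rows = []
    for i in range(n_counties):
        for year in years:
            for ind in scheme.indicator_ids:
                rows.append((f"C{i:02d}", year, ind, float(rng.uniform(1, 100))))
    return pd.DataFrame(rows, columns=["county", "year", "indicator", "value"])


@pytest.fixture
def panel_df():
    return make_panel_df(n_counties=6, years=(2020, 2021), seed=7)
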