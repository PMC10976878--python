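import numpy as np
import pytest
import xarray as xr

from rxsmoke import DomainGrid, SyntheticConfig, synthetic


@pytest.fixture(scope="session")
def grid():
    return DomainGrid(10, 10, 12.0)


@pytest.fixture(scope="session")
def config():
    return SyntheticConfig(seed=7, n_fires=50)


@pytest.fixture(scope="session")
def met(grid, config):
    return synthetic.generate_meteorology(grid, config)


@pytest.fixture(scope="session")
def fires(grid, config):
    return synthetic.generate_fires(grid, config)


@pytest.fixture(scope="session")
def population(grid, config):
    return synthetic.generate_population(grid, config)


@pytest.fixture(scope="session")
def fuelbeds(grid, config):
    return synthetic.generate_fuelbeds(grid, config)


def make_met(values: dict, days, n_rows=1, n_cols=1) -> xr.Dataset:
    """Hand-written meteorology: values maps var -> per-day scalars."""
    days = np.asarray(days)
    data = {}
    defaults = {
        "wind_speed": 3.0,
        "wind_dir": 0.0,
        "temp_c": 15.0,
        "rh": 0.35,
        "soil_moisture": 0.2,
    }
    for var, default in defaults.items():
        vals = np.asarray(values.get(var, np.full(len(days), default)), dtype=float)
        data[var] = (
            ("day", "row", "col"),
            np.broadcast_to(vals[:, None, None], (len(days), n_rows, n_cols)).copy(),
        )
    return xr.Dataset(
        data,
        coords={"day": days, "row": np.arange(n_rows), "col": np.arange(n_cols)},
    )


@pytest.fixture(scope="session")
def demo_bundle():
    """End-to-end 20x20, 200-fire comparison used by several suites."""
    from rxsmoke import pipeline

    return pipeline.run(pipeline.RunConfig(seed=1, n_rows=20, n_cols=20, n_fires=200))
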