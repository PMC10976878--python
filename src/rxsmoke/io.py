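"""File I/O: NetCDF/CSV writers and config loading.

Gridded fields (meteorology, emissions, concentrations, population) are
written as classic NetCDF with projected x/y km coordinates; tabular
data (fires, fuel beds, schedules, stations, stats) as CSV; configs are
TOML or YAML.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import xarray as xr
import yaml

from .grid import DomainGrid

_NC_ENGINE = "scipy"  # classic NetCDF3; no external netCDF library needed


def _with_coords(ds: xr.Dataset | xr.DataArray, grid: DomainGrid | None):
    if grid is None:
        return ds
    xx, yy = grid.cell_centers()
    return ds.assign_coords(
        x=("col", xx[0, :]), y=("row", yy[:, 0])
    )


def write_netcdf(data: xr.Dataset | xr.DataArray, path, grid: DomainGrid | None = None):
    """Write a gridded field with projected km coordinates attached."""
    data = _with_coords(data, grid)
    if isinstance(data, xr.DataArray):
        data = data.to_dataset(name=data.name or "field")
    data.to_netcdf(path, engine=_NC_ENGINE)


def read_netcdf(path) -> xr.Dataset:
    return xr.load_dataset(path, engine=_NC_ENGINE)


def write_population(population: np.ndarray, path, grid: DomainGrid):
    da = xr.DataArray(
        population.astype("int32"),
        dims=("row", "col"),
        name="population",
        attrs={"units": "persons"},
    )
    write_netcdf(da, path, grid)


def load_config(path) -> dict:
    """Load a TOML or YAML config mapping."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            return yaml.safe_load(fh) or {}
    raise ValueError(f"unsupported config format: {path.suffix}")


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
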