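"""Seeded synthetic inputs for the fire-scenario pipeline.

Generates every input the pipeline consumes — daily gridded meteorology,
fire events, population, and fuel beds — with the statistical structure
the downstream stages rely on:

* seasonal meteorology in which a large share of spring/fall days meet
  prescribed-burn criteria while summer days almost never do (summer is
  hot, dry and has low soil moisture);
* fire occurrence concentrated in the May-September wildfire season with
  heavy-tailed (lognormal) sizes, where large events span consecutive
  days and sometimes two cells;
* spatially clustered population;
* per-cell fuel beds mixing canopy/shrub/nonwoody/woody/duff loadings so
  that forest, shrubland and grassland cover types all occur.

All generators are deterministic functions of (config.seed, grid shape):
the same seed gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .grid import DomainGrid
from .seasons import DAYS_PER_YEAR, MONTH_LENGTHS, MONTH_STARTS, season_of


class ConfigurationError(ValueError):
    """Raised for invalid synthetic-data configuration."""


#: per-season meteorology: (mean, sd) per variable, plus wind direction
#: (degrees clockwise from north, direction of transport) mean and spread.
#: Spring/fall are mild and moist enough that burn-window criteria pass
#: often; summer fails on temperature, humidity and soil moisture.
DEFAULT_MET_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "spring": {
        "wind_speed": (3.5, 1.5),
        "temp_c": (15.0, 6.0),
        "rh": (0.35, 0.08),
        "soil_moisture": (0.22, 0.05),
        "wind_dir": (270.0, 40.0),
    },
    "summer": {
        "wind_speed": (4.0, 1.5),
        "temp_c": (32.0, 5.0),
        "rh": (0.15, 0.07),
        "soil_moisture": (0.08, 0.04),
        "wind_dir": (45.0, 30.0),
    },
    "fall": {
        "wind_speed": (3.5, 1.5),
        "temp_c": (17.0, 6.0),
        "rh": (0.35, 0.08),
        "soil_moisture": (0.22, 0.05),
        "wind_dir": (180.0, 40.0),
    },
    "winter": {
        "wind_speed": (4.5, 2.0),
        "temp_c": (8.0, 5.0),
        "rh": (0.70, 0.10),
        "soil_moisture": (0.35, 0.08),
        "wind_dir": (225.0, 60.0),
    },
}

#: monthly fire-ignition weights, concentrated May-September.
DEFAULT_SEASON_WEIGHTS = (
    0.005, 0.005, 0.01, 0.02, 0.10, 0.17, 0.25, 0.25, 0.13, 0.04, 0.01, 0.005,
)

MET_VARS = ("wind_speed", "temp_c", "rh", "soil_moisture", "wind_dir")


def _default_fire_size() -> dict[str, float]:
    # lognormal sized so the mean fire is ~1.4 km^2 (140 ha) with a heavy
    # right tail: mu = ln(mean) - sigma^2/2
    sigma = 1.5
    return {"mu": float(np.log(1.4) - sigma**2 / 2), "sigma": sigma}


def _default_population() -> dict[str, float]:
    return {"total": 1_000_000, "n_clusters": 4, "dispersion": 2.0}


def _default_fuel() -> dict[str, object]:
    return {
        # mean total loading kg/km^2 and lognormal sd of its log
        "total_mean": 2.0e6,
        "total_sigma": 0.5,
        "cover_mix": {"forest": 0.5, "shrubland": 0.3, "grassland": 0.2},
    }


@dataclass
class SyntheticConfig:
    """Configuration for all synthetic generators.

    ``season_weights`` are 12 monthly ignition probabilities (normalized
    internally; must be non-negative with positive sum). ``met_params``
    maps season -> variable -> (mean, sd). Same seed implies bit-identical
    outputs from every generator.
    """

    seed: int = 0
    year: int = 2012
    n_fires: int = 200
    fire_size_params: dict = field(default_factory=_default_fire_size)
    season_weights: tuple = DEFAULT_SEASON_WEIGHTS
    met_params: dict = field(default_factory=lambda: DEFAULT_MET_PARAMS)
    population_params: dict = field(default_factory=_default_population)
    fuel_params: dict = field(default_factory=_default_fuel)
    smooth_sigma: float = 2.0  # spatial smoothing length, cells
    span_threshold_km2: float = 20.0  # fires above this may span days
    max_span_days: int = 4
    p_multicell: float = 0.5  # chance a spanning fire occupies 2 cells

    def __post_init__(self) -> None:
        w = np.asarray(self.season_weights, dtype=float)
        if w.shape != (12,) or np.any(w < 0) or w.sum() <= 0:
            raise ConfigurationError(
                "season_weights must be 12 non-negative values with positive sum"
            )
        self.season_weights = tuple(w / w.sum())
        for season, params in self.met_params.items():
            if season not in DEFAULT_MET_PARAMS:
                raise ConfigurationError(f"unknown season {season!r}")
            for var, (mean, sd) in params.items():
                if var not in MET_VARS:
                    raise ConfigurationError(f"unknown met variable {var!r}")
                if sd < 0:
                    raise ConfigurationError(
                        f"negative sd for {season}/{var}: {sd}"
                    )
        if set(self.met_params) != set(DEFAULT_MET_PARAMS):
            raise ConfigurationError("met_params must cover all four seasons")
        if self.n_fires < 0:
            raise ConfigurationError("n_fires must be >= 0")
        if self.population_params.get("n_clusters", 1) < 1:
            raise ConfigurationError("need at least one population cluster")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive streams per generator
    return np.random.default_rng([config.seed, stream])


def _smooth_unit_field(rng, shape, sigma) -> np.ndarray:
    """Spatially smoothed standard-normal field, rescaled to unit variance."""
    raw = rng.standard_normal(shape)
    if sigma <= 0 or min(shape) == 1:
        return raw
    sm = ndimage.gaussian_filter(raw, sigma=sigma, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_meteorology(grid: DomainGrid, config: SyntheticConfig) -> xr.Dataset:
    """Daily per-cell meteorology for one 365-day year.

    Returns an xarray Dataset with dims (day, row, col) and variables
    wind_speed (m/s), wind_dir (deg, transport direction clockwise from
    north), temp_c (degC), rh (fraction) and soil_moisture (m3/m3).
    RH and soil moisture are truncated to [0, 1]; wind speed to >= 0.
    """
    rng = _rng(config, 1)
    days = np.arange(1, DAYS_PER_YEAR + 1)
    seasons = season_of(days)
    shape = (DAYS_PER_YEAR, grid.n_rows, grid.n_cols)
    out = {v: np.empty(shape) for v in MET_VARS}
    for d_idx in range(DAYS_PER_YEAR):
        params = config.met_params[str(seasons[d_idx])]
        for var in MET_VARS:
            mean, sd = params[var]
            fld = _smooth_unit_field(rng, (grid.n_rows, grid.n_cols), config.smooth_sigma)
            out[var][d_idx] = mean + sd * fld
    out["wind_speed"] = np.clip(out["wind_speed"], 0.0, None)
    out["rh"] = np.clip(out["rh"], 0.0, 1.0)
    out["soil_moisture"] = np.clip(out["soil_moisture"], 0.0, 1.0)
    out["wind_dir"] = np.mod(out["wind_dir"], 360.0)
    ds = xr.Dataset(
        {v: (("day", "row", "col"), out[v]) for v in MET_VARS},
        coords={"day": days, "row": np.arange(grid.n_rows), "col": np.arange(grid.n_cols)},
        attrs={"year": config.year, "cell_size_km": grid.cell_size},
    )
    ds["wind_speed"].attrs["units"] = "m s-1"
    ds["temp_c"].attrs["units"] = "degC"
    ds["rh"].attrs["units"] = "1"
    ds["soil_moisture"].attrs["units"] = "m3 m-3"
    ds["wind_dir"].attrs["units"] = "degrees (transport direction, CW from north)"
    return ds


FIRE_COLUMNS = ("event_id", "day", "row", "col", "area_km2", "fuelbed_id")


def generate_fires(grid: DomainGrid, config: SyntheticConfig) -> pd.DataFrame:
    """Synthetic fire events as a DataFrame with columns FIRE_COLUMNS.

    One row is one (event, day, cell) burn record. Event dates follow the
    monthly ignition weights; sizes are lognormal (heavy-tailed); events
    larger than ``span_threshold_km2`` spread over consecutive days and
    sometimes over two adjacent cells. ``fuelbed_id`` is the flat cell
    index, linking each record to its cell's fuel bed.
    """
    rng = _rng(config, 2)
    rows: list[tuple] = []
    mu = config.fire_size_params["mu"]
    sigma = config.fire_size_params["sigma"]
    months = rng.choice(12, size=config.n_fires, p=np.asarray(config.season_weights))
    for event_id in range(config.n_fires):
        m = int(months[event_id])
        day0 = MONTH_STARTS[m] + int(rng.integers(MONTH_LENGTHS[m]))
        area = float(rng.lognormal(mu, sigma))
        r = int(rng.integers(grid.n_rows))
        c = int(rng.integers(grid.n_cols))
        if area <= config.span_threshold_km2:
            rows.append((event_id, day0, r, c, area))
            continue
        n_days = min(
            1 + int(area // config.span_threshold_km2), config.max_span_days
        )
        n_days = min(n_days, DAYS_PER_YEAR - day0 + 1)
        parts = rng.dirichlet(np.ones(n_days)) * area
        two_cells = n_days > 1 and rng.random() < config.p_multicell
        r2, c2 = r, c
        if two_cells:  # neighbouring cell, clipped to the grid
            if c + 1 < grid.n_cols:
                c2 = c + 1
            elif c > 0:
                c2 = c - 1
            elif r + 1 < grid.n_rows:
                r2 = r + 1
        for k in range(n_days):
            in_second = two_cells and k >= n_days // 2
            rows.append(
                (event_id, day0 + k, r2 if in_second else r,
                 c2 if in_second else c, float(parts[k]))
            )
    if not rows:
        return pd.DataFrame(
            {c: pd.Series(dtype=float if c == "area_km2" else int) for c in FIRE_COLUMNS}
        )
    df = pd.DataFrame(rows, columns=FIRE_COLUMNS[:-1])
    df["fuelbed_id"] = df["row"] * grid.n_cols + df["col"]
    return df.astype(
        {"event_id": int, "day": int, "row": int, "col": int,
         "area_km2": float, "fuelbed_id": int}
    )


def generate_population(grid: DomainGrid, config: SyntheticConfig) -> np.ndarray:
    """Clustered integer population counts, shape (n_rows, n_cols).

    Cell probabilities are a mixture of isotropic Gaussians around
    uniformly placed cluster centres; the configured total is conserved
    exactly by a multinomial draw. Zero dispersion puts each cluster's
    mass in a single cell.
    """
    rng = _rng(config, 3)
    p = config.population_params
    total = int(p["total"])
    k = int(p["n_clusters"])
    disp = float(p["dispersion"])
    centers_r = rng.uniform(0, grid.n_rows, size=k)
    centers_c = rng.uniform(0, grid.n_cols, size=k)
    rr, cc = np.meshgrid(
        np.arange(grid.n_rows) + 0.5, np.arange(grid.n_cols) + 0.5, indexing="ij"
    )
    prob = np.zeros((grid.n_rows, grid.n_cols))
    for i in range(k):
        if disp > 0:
            d2 = (rr - centers_r[i]) ** 2 + (cc - centers_c[i]) ** 2
            prob += np.exp(-d2 / (2 * disp**2))
        else:
            r0 = min(int(centers_r[i]), grid.n_rows - 1)
            c0 = min(int(centers_c[i]), grid.n_cols - 1)
            prob[r0, c0] += 1.0
    prob /= prob.sum()
    counts = rng.multinomial(total, prob.ravel()).reshape(grid.n_rows, grid.n_cols)
    return counts


#: Dirichlet concentration of category shares by dominant cover type.
_FUEL_ALPHAS = {
    "forest": {"canopy": 30, "shrub": 5, "nonwoody": 5, "woody": 35, "duff": 25},
    "shrubland": {"canopy": 5, "shrub": 55, "nonwoody": 10, "woody": 15, "duff": 15},
    "grassland": {"canopy": 2, "shrub": 10, "nonwoody": 60, "woody": 8, "duff": 20},
}

FUEL_CATEGORIES = ("canopy", "shrub", "nonwoody", "woody", "duff")


def generate_fuelbeds(grid: DomainGrid, config: SyntheticConfig) -> pd.DataFrame:
    """Per-cell fuel-bed loadings (kg/km^2) in five categories.

    Each cell draws a dominant cover type from the configured mixture and
    category shares from a type-specific Dirichlet, scaled by a lognormal
    total loading. Columns: fuelbed_id, row, col, canopy, shrub,
    nonwoody, woody, duff.
    """
    rng = _rng(config, 4)
    fp = config.fuel_params
    mix = fp["cover_mix"]
    types = list(mix)
    weights = np.asarray([mix[t] for t in types], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ConfigurationError("cover_mix weights must be non-negative, sum > 0")
    weights /= weights.sum()
    n = grid.n_cells
    chosen = rng.choice(len(types), size=n, p=weights)
    totals = rng.lognormal(
        np.log(fp["total_mean"]) - fp["total_sigma"] ** 2 / 2, fp["total_sigma"], size=n
    )
    loadings = np.empty((n, len(FUEL_CATEGORIES)))
    for i in range(n):
        alphas = _FUEL_ALPHAS[types[chosen[i]]]
        shares = rng.dirichlet([alphas[c] for c in FUEL_CATEGORIES])
        loadings[i] = shares * totals[i]
    cell_ids = np.arange(n)
    df = pd.DataFrame(loadings, columns=list(FUEL_CATEGORIES))
    df.insert(0, "col", cell_ids % grid.n_cols)
    df.insert(0, "row", cell_ids // grid.n_cols)
    df.insert(0, "fuelbed_id", cell_ids)
    return df


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
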