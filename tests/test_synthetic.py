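"""Synthetic-input generators: determinism, ranges, seasonal structure."""

import numpy as np
import pandas as pd
import pytest

from rxsmoke import DomainGrid, SyntheticConfig, synthetic
from rxsmoke.scheduler import BurnWindowCriteria
from rxsmoke.seasons import days_in_months
from rxsmoke.synthetic import ConfigurationError


@pytest.mark.parametrize(
    "generator",
    [
        synthetic.generate_meteorology,
        synthetic.generate_fires,
        synthetic.generate_population,
        synthetic.generate_fuelbeds,
    ],
)
def test_same_seed_bit_identical(grid, config, generator):
    a = generator(grid, config)
    b = generator(grid, SyntheticConfig(seed=config.seed, n_fires=config.n_fires))
    if isinstance(a, pd.DataFrame):
        pd.testing.assert_frame_equal(a, b)
    elif isinstance(a, np.ndarray):
        np.testing.assert_array_equal(a, b)
    else:
        assert a.identical(b)


def test_met_physical_ranges(met):
    assert float(met["wind_speed"].min()) >= 0
    assert 0 <= float(met["rh"].min()) and float(met["rh"].max()) <= 1
    assert 0 <= float(met["soil_moisture"].min()) <= float(met["soil_moisture"].max()) <= 1


def test_zero_variance_met_is_uniform_within_season(grid):
    params = {
        s: {v: (m, 0.0) for v, (m, _) in p.items()}
        for s, p in synthetic.DEFAULT_MET_PARAMS.items()
    }
    cfg = SyntheticConfig(seed=3, met_params=params)
    met = synthetic.generate_meteorology(grid, cfg)
    july = met.sel(day=days_in_months([7]))
    assert float(july["temp_c"].std()) == 0.0
    assert float(july["wind_speed"].std()) == 0.0


def _strict_pass_fraction(met, months):
    """Independent brute-force burn-window count, straight off the table."""
    sub = met.sel(day=days_in_months(months))
    w = sub["wind_speed"].values
    t = sub["temp_c"].values
    rh = sub["rh"].values
    sm = sub["soil_moisture"].values
    ok = (w < 5.36) & (t < 29.5) & (rh >= 0.25) & (rh <= 0.45) & (sm >= 0.15) & (sm <= 0.3)
    return ok.mean()


def test_april_strict_window_fraction(config):
    grid = DomainGrid(20, 20)
    met = synthetic.generate_meteorology(grid, config)
    frac = _strict_pass_fraction(met, [4])
    assert 0.3 <= frac <= 1.0


def test_summer_rarely_passes_strict_window(met):
    assert _strict_pass_fraction(met, [6, 7, 8]) < 0.05


def test_invalid_season_params_rejected():
    bad = {s: dict(p) for s, p in synthetic.DEFAULT_MET_PARAMS.items()}
    bad["summer"]["wind_speed"] = (4.0, -1.0)
    with pytest.raises(ConfigurationError):
        SyntheticConfig(met_params=bad)
    with pytest.raises(ConfigurationError):
        SyntheticConfig(season_weights=(1.0,) * 11)


def test_no_fires(grid):
    fires = synthetic.generate_fires(grid, SyntheticConfig(seed=1, n_fires=0))
    assert len(fires) == 0
    assert list(fires.columns) == list(synthetic.FIRE_COLUMNS)


def test_fire_total_area_near_analytic_mean(grid):
    cfg = SyntheticConfig(seed=11, n_fires=500)
    fires = synthetic.generate_fires(grid, cfg)
    mu, sigma = cfg.fire_size_params["mu"], cfg.fire_size_params["sigma"]
    expected = cfg.n_fires * np.exp(mu + sigma**2 / 2)  # lognormal mean
    assert 0.5 * expected <= fires.groupby("event_id")["area_km2"].sum().sum() <= 1.5 * expected


def test_fire_dates_follow_season_weights(grid):
    cfg = SyntheticConfig(seed=5, n_fires=800)
    fires = synthetic.generate_fires(grid, cfg)
    first_days = fires.groupby("event_id")["day"].min()
    from rxsmoke.seasons import month_of

    months = month_of(first_days.to_numpy())
    summerish = np.isin(months, [5, 6, 7, 8, 9]).mean()
    assert summerish > 0.8  # weights concentrate ignitions May-September


def test_large_fires_span_days_and_cells(grid):
    cfg = SyntheticConfig(seed=2, n_fires=300)
    fires = synthetic.generate_fires(grid, cfg)
    per_event = fires.groupby("event_id").agg(
        n=("day", "size"), days=("day", lambda d: d.max() - d.min() + 1)
    )
    multi = per_event[per_event["n"] > 1]
    assert len(multi) > 0
    assert (multi["days"] == multi["n"]).all()  # consecutive days
    cells_per_event = fires.groupby("event_id")[["row", "col"]].nunique().max(axis=1)
    assert cells_per_event.max() == 2  # some events occupy two cells


def test_population_conserved_and_clustered(grid, config, population):
    assert population.sum() == config.population_params["total"]
    assert population.min() >= 0
    # clustered: top decile of cells holds at least twice a uniform share
    flat = np.sort(population.ravel())[::-1]
    assert flat[: len(flat) // 10].sum() > 0.2 * population.sum()


def test_single_cluster_zero_dispersion(grid):
    cfg = SyntheticConfig(
        seed=4, population_params={"total": 12345, "n_clusters": 1, "dispersion": 0.0}
    )
    pop = synthetic.generate_population(grid, cfg)
    assert pop.sum() == 12345
    assert (pop > 0).sum() == 1


def test_fuelbeds_cover_all_three_types(grid, fuelbeds):
    from rxsmoke.fuels import classify_fuelbed

    big_grid = DomainGrid(20, 20)
    beds = synthetic.generate_fuelbeds(big_grid, SyntheticConfig(seed=9))
    covers = {
        classify_fuelbed(r[list(synthetic.FUEL_CATEGORIES)])
        for _, r in beds.iterrows()
    }
    assert covers == {"forest", "shrubland", "grassland"}
    assert (fuelbeds[list(synthetic.FUEL_CATEGORIES)].to_numpy() >= 0).all()


def test_forest_only_mixture(grid):
    from rxsmoke.fuels import classify_fuelbed

    cfg = SyntheticConfig(seed=8)
    cfg.fuel_params["cover_mix"] = {"forest": 1.0}
    beds = synthetic.generate_fuelbeds(grid, cfg)
    assert all(
        classify_fuelbed(r[list(synthetic.FUEL_CATEGORIES)]) == "forest"
        for _, r in beds.iterrows()
    )


def test_every_fire_finds_a_strict_window_day(grid, config, met, fires):
    """Structural adequacy: the generated weather leaves essentially no
    fire without a strict-tier prescribed-burn day."""
    from rxsmoke import scheduler

    cells = fires[["row", "col"]].drop_duplicates()
    ok = sum(
        len(scheduler.candidate_days(r.row, r.col, met)) > 0
        for r in cells.itertuples()
    )
    assert ok / len(cells) >= 0.9
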