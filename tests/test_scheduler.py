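"""Burn-window filtering, day assignment and scenario construction."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_met
from rxsmoke import scheduler, synthetic
from rxsmoke.grid import DomainGrid
from rxsmoke.scheduler import (
    BurnWindowCriteria,
    NoBurnCalendar,
    SchedulingError,
    assign_day,
    build_scenario,
    candidate_days,
    collapse_multiday,
    screen_high_exposure_days,
)
from rxsmoke.seasons import burn_season_days, doy, month_of


def test_criteria_validation():
    with pytest.raises(ValueError):
        BurnWindowCriteria(rh_range=(0.5, 0.4))
    with pytest.raises(ValueError):
        BurnWindowCriteria(fallback_max_wind=1.0)


def _five_day_met():
    # five hand-written spring days: only days 91 and 93 pass strict
    days = [90, 91, 92, 93, 94]
    return days, make_met(
        {
            "wind_speed": [2.0, 3.0, 4.0, 2.1, 1.0],
            "temp_c": [15, 15, 15, 15, 35],  # day 94 too hot
            "rh": [0.60, 0.35, 0.35, 0.40, 0.35],  # day 90 too humid
            "soil_moisture": [0.2, 0.2, 0.5, 0.2, 0.2],  # day 92 too wet
        },
        days,
    )


def test_candidate_days_filters_and_sorts_by_wind():
    days, met = _five_day_met()
    # restrict the season to the five constructed days via the met calendar
    cands = candidate_days(0, 0, met.reindex(day=burn_season_days(), fill_value=99.0))
    assert list(cands["day"]) == [93, 91]  # lowest wind first (2.1 < 3.0)


def _full_met(values_by_day: dict, default=None):
    """Met covering all burn-season days; unspecified days fail strict."""
    days = burn_season_days()
    base = {
        "wind_speed": np.full(len(days), 99.0),
        "temp_c": np.full(len(days), 15.0),
        "rh": np.full(len(days), 0.35),
        "soil_moisture": np.full(len(days), 0.2),
    }
    if default:
        for k, v in default.items():
            base[k][:] = v
    idx = {int(d): i for i, d in enumerate(days)}
    for d, vals in values_by_day.items():
        for k, v in vals.items():
            base[k][idx[d]] = v
    return make_met(base, days)


def test_assign_day_minimum_wind_and_tie_break():
    met = _full_met({100: {"wind_speed": 3.0}, 150: {"wind_speed": 2.1}})
    assert assign_day(0, 0, met) == (150, "strict")
    met_tie = _full_met({100: {"wind_speed": 2.1}, 150: {"wind_speed": 2.1}})
    assert assign_day(0, 0, met_tie) == (100, "strict")  # earliest date


def test_assign_day_fallback_tier():
    # no strict day anywhere; day 250 passes only the relaxed bounds
    met = _full_met({250: {"wind_speed": 6.0, "rh": 0.55}})
    day, tier = assign_day(0, 0, met)
    assert (day, tier) == (250, "fallback")


def test_assign_day_fails_when_no_day_passes():
    met = _full_met({})
    with pytest.raises(SchedulingError):
        assign_day(0, 0, met)


def test_no_burn_calendar_excludes_days():
    met = _full_met({100: {"wind_speed": 2.0}, 150: {"wind_speed": 3.0}})
    cal = NoBurnCalendar(((100, 100),))
    assert assign_day(0, 0, met, no_burn=None)[0] == 100
    assert assign_day(0, 0, met, no_burn=cal)[0] == 150
    # and Rx2 candidates are a subset of Rx1 candidates
    rx1 = set(candidate_days(0, 0, met)["day"])
    rx2 = set(candidate_days(0, 0, met, no_burn=cal)["day"])
    assert rx2 <= rx1


def test_rx2_2012_preset_calendar():
    cal = NoBurnCalendar.rx2_2012()
    assert doy(4, 27) in cal.days and doy(5, 2) in cal.days
    assert doy(11, 5) in cal.days and doy(11, 6) not in cal.days
    assert len(cal) == 6 + 6 + 3 + 4


def _fire_frame(rows):
    return pd.DataFrame(rows, columns=["event_id", "day", "row", "col", "area_km2"])


def test_collapse_multiday_single_cell():
    fires = _fire_frame([(0, 150, 2, 3, 1.0), (0, 151, 2, 3, 2.0), (0, 152, 2, 3, 3.0)])
    out = collapse_multiday(fires)
    assert len(out) == 1
    assert out.loc[0, "area_km2"] == 6.0
    assert out.loc[0, "day"] == 150
    assert bool(out.loc[0, "collapsed"])


def test_collapse_keeps_multicell_events_separate():
    fires = _fire_frame([(0, 150, 2, 3, 1.0), (0, 151, 2, 4, 2.0)])
    out = collapse_multiday(fires)
    assert len(out) == 2
    assert not out["collapsed"].any()
    single = _fire_frame([(1, 10, 0, 0, 5.0)])
    assert len(collapse_multiday(single)) == 1


def test_build_scenario_conserves_area_and_seasons(grid, config, met, fires):
    for mode in ("rx1", "rx2"):
        sched = build_scenario(
            fires, met, mode=mode, no_burn=NoBurnCalendar.rx2_2012()
        )
        assert sched["area_km2"].sum() == pytest.approx(fires["area_km2"].sum(), rel=1e-12)
        months = month_of(sched["day"].to_numpy())
        assert np.isin(months, [3, 4, 5, 9, 10, 11]).all()


def test_build_scenario_empty_input(met):
    out = build_scenario(_fire_frame([]), met)
    assert len(out) == 0


def test_assigned_days_repass_their_tier(grid, config, met, fires):
    """Feasibility: every assigned day re-passes its tier's filters in an
    independent check straight off the meteorology table."""
    crit = BurnWindowCriteria()
    sched = build_scenario(fires, met, crit, mode="rx1")
    for f in sched.itertuples():
        cell = met.sel(day=f.day).isel(row=f.row, col=f.col)
        ok = crit.passes(
            np.array(cell["wind_speed"]), np.array(cell["temp_c"]),
            np.array(cell["rh"]), np.array(cell["soil_moisture"]), tier=f.tier,
        )
        assert bool(ok)


def test_assignment_matches_exhaustive_search(grid, config, met, fires):
    """Oracle equivalence on a 10x10 grid: filter every burn-season day
    by hand, take the minimum wind, break ties by date."""
    crit = BurnWindowCriteria()
    sched = build_scenario(fires, met, crit, mode="rx1")
    days = burn_season_days()
    for f in sched.itertuples():
        cell = met.isel(row=f.row, col=f.col).sel(day=days)
        for tier in ("strict", "fallback"):
            ok = crit.passes(
                cell["wind_speed"].values, cell["temp_c"].values,
                cell["rh"].values, cell["soil_moisture"].values, tier=tier,
            )
            if ok.any():
                wind = cell["wind_speed"].values[ok]
                best = days[ok][np.flatnonzero(wind == wind.min())[0]]
                assert (f.day, f.tier) == (best, tier)
                break
        else:
            pytest.fail("scheduler placed a fire the oracle could not")


def test_rx1_rx2_differ_only_where_calendar_bites(grid, config, met, fires):
    rx1 = build_scenario(fires, met, mode="rx1")
    cal = NoBurnCalendar.from_days(rx1["day"].unique()[:2])
    rx2 = build_scenario(fires, met, mode="rx2", no_burn=cal)
    moved = rx1["day"].isin(cal.days)
    assert (rx2.loc[moved, "day"] != rx1.loc[moved, "day"]).all()
    assert (rx2.loc[~moved, "day"] == rx1.loc[~moved, "day"]).all()


def test_screen_high_exposure_quantile_and_edges(grid, config, met, fires, population):
    cal = screen_high_exposure_days(fires, met, population, grid, quantile=0.9)
    n_days = len(burn_season_days())
    # at most (1-q) of candidate days excluded, up to ties
    assert 0 < len(cal) <= int(np.ceil(0.1 * n_days)) + 5
    assert screen_high_exposure_days(fires, met, population, grid, quantile=1.0).days == frozenset()
    empty = fires.iloc[0:0]
    assert len(screen_high_exposure_days(empty, met, population, grid)) == 0


def test_screen_excludes_the_dominant_downwind_day(config):
    """Population concentrated in one cell immediately downwind on exactly
    one day's wind: that day must be screened out at any q < 1."""
    grid = DomainGrid(5, 5)
    days = burn_season_days()
    wind_dir = np.zeros(len(days))
    wind_speed = np.full(len(days), 0.5)
    special = 60  # index into burn-season days
    wind_dir[special] = 90.0  # blow east toward the populated cell
    wind_speed[special] = 3.0
    met = make_met(
        {"wind_speed": wind_speed, "wind_dir": wind_dir}, days, n_rows=5, n_cols=5
    )
    pop = np.zeros((5, 5))
    pop[2, 4] = 1000.0
    fires = pd.DataFrame(
        [(0, 200, 2, 0, 1.0)], columns=["event_id", "day", "row", "col", "area_km2"]
    )
    cal = screen_high_exposure_days(fires, met, pop, grid, quantile=0.95)
    assert int(days[special]) in cal.days
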