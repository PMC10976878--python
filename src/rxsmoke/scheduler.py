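"""Prescribed-burn scenario scheduling.

Each wildfire's burned area is moved onto a day suitable for prescribed
burning in that fire's grid cell. Candidate days lie in the spring
(March-May) or fall (September-November) burn seasons and must satisfy
the strict burn-window criteria: 20-ft wind speed < 5.36 m/s (12 mph),
temperature < 29.5 degC (85 degF), relative humidity in [0.25, 0.45],
and soil moisture in [0.15, 0.3] m3/m3. Among passing days the one with
the lowest wind speed is chosen (minimizing escape risk); with no
passing day a relaxed tier applies (wind < 15 mph, RH up to 0.6, other
criteria unchanged). Wind ties break to the earliest date.

The Rx1 scenario applies only these environmental filters; Rx2 removes a
"no burn" calendar of high-population-exposure days before filtering.
Multi-day events confined to a single cell collapse to one day; events
spanning multiple cells keep independent per-cell records. Total burned
area is always conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import xarray as xr

from .grid import DomainGrid
from .seasons import burn_season_days, doy


class SchedulingError(RuntimeError):
    """Raised when a fire cannot be placed on any candidate day."""


@dataclass(frozen=True)
class BurnWindowCriteria:
    """Meteorological burn-window thresholds.

    Strict tier: wind < max_wind, temp < max_temp, RH within rh_range,
    soil moisture within soil_moisture_range. Fallback tier relaxes only
    wind (< fallback_max_wind = 15 mph) and RH (<= fallback_rh_max).
    """

    max_wind: float = 5.36  # m/s (12 mph)
    max_temp: float = 29.5  # degC (85 degF)
    rh_range: tuple[float, float] = (0.25, 0.45)
    soil_moisture_range: tuple[float, float] = (0.15, 0.30)
    fallback_max_wind: float = 6.7056  # m/s (15 mph)
    fallback_rh_max: float = 0.60

    def __post_init__(self) -> None:
        if self.rh_range[0] > self.rh_range[1]:
            raise ValueError("rh_range must be ordered")
        if self.soil_moisture_range[0] > self.soil_moisture_range[1]:
            raise ValueError("soil_moisture_range must be ordered")
        if self.fallback_max_wind < self.max_wind:
            raise ValueError("fallback wind bound must be >= strict bound")
        if self.fallback_rh_max < self.rh_range[1]:
            raise ValueError("fallback RH bound must be >= strict upper RH")

    def passes(
        self,
        wind: np.ndarray,
        temp: np.ndarray,
        rh: np.ndarray,
        soil_moisture: np.ndarray,
        tier: str = "strict",
    ) -> np.ndarray:
        """Boolean mask of days passing the given tier's criteria."""
        base = (
            (temp < self.max_temp)
            & (soil_moisture >= self.soil_moisture_range[0])
            & (soil_moisture <= self.soil_moisture_range[1])
        )
        if tier == "strict":
            return (
                base
                & (wind < self.max_wind)
                & (rh >= self.rh_range[0])
                & (rh <= self.rh_range[1])
            )
        if tier == "fallback":
            return (
                base
                & (wind < self.fallback_max_wind)
                & (rh >= self.rh_range[0])
                & (rh <= self.fallback_rh_max)
            )
        raise ValueError(f"unknown tier {tier!r}")


#: fixed no-burn periods used by the 2012 Rx2 study scenario
RX2_2012_NO_BURN = (
    (doy(4, 27), doy(5, 2)),
    (doy(5, 28), doy(6, 2)),
    (doy(10, 26), doy(10, 28)),
    (doy(11, 2), doy(11, 5)),
)


@dataclass(frozen=True)
class NoBurnCalendar:
    """Day-of-year intervals excluded from prescribed-burn candidacy."""

    intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        for a, b in self.intervals:
            if not (1 <= a <= b <= 365):
                raise ValueError(f"bad no-burn interval ({a}, {b})")

    @classmethod
    def rx2_2012(cls) -> "NoBurnCalendar":
        return cls(RX2_2012_NO_BURN)

    @classmethod
    def from_days(cls, days: Iterable[int]) -> "NoBurnCalendar":
        days = sorted(set(int(d) for d in days))
        if not days:
            return cls(())
        intervals, start, prev = [], days[0], days[0]
        for d in days[1:]:
            if d == prev + 1:
                prev = d
                continue
            intervals.append((start, prev))
            start = prev = d
        intervals.append((start, prev))
        return cls(tuple(intervals))

    @property
    def days(self) -> frozenset[int]:
        out: set[int] = set()
        for a, b in self.intervals:
            out.update(range(a, b + 1))
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.days)


def _cell_met(met: xr.Dataset, row: int, col: int, days: np.ndarray):
    sub = met.isel(row=row, col=col).sel(day=days)
    return (
        sub["wind_speed"].values,
        sub["temp_c"].values,
        sub["rh"].values,
        sub["soil_moisture"].values,
    )


def candidate_days(
    row: int,
    col: int,
    met: xr.Dataset,
    criteria: BurnWindowCriteria = BurnWindowCriteria(),
    no_burn: NoBurnCalendar | None = None,
    tier: str = "strict",
) -> pd.DataFrame:
    """Burn-season days passing the criteria for one grid cell.

    Returns a frame (day, wind_speed) sorted by ascending wind speed,
    with ties in wind broken by the earlier date. No-burn days are
    removed before filtering.
    """
    days = burn_season_days()
    if no_burn is not None and len(no_burn):
        blocked = no_burn.days
        days = days[~np.isin(days, list(blocked))]
    wind, temp, rh, sm = _cell_met(met, row, col, days)
    ok = criteria.passes(wind, temp, rh, sm, tier=tier)
    df = pd.DataFrame({"day": days[ok], "wind_speed": wind[ok]})
    return df.sort_values(
        ["wind_speed", "day"], kind="stable", ignore_index=True
    )


def assign_day(
    row: int,
    col: int,
    met: xr.Dataset,
    criteria: BurnWindowCriteria = BurnWindowCriteria(),
    no_burn: NoBurnCalendar | None = None,
) -> tuple[int, str]:
    """Pick the burn day for a fire in cell (row, col).

    Returns (day_of_year, tier): the minimum-wind strict-tier day if any
    exists, else the minimum-wind fallback-tier day. Raises
    SchedulingError when both tiers are empty.
    """
    for tier in ("strict", "fallback"):
        cands = candidate_days(row, col, met, criteria, no_burn, tier=tier)
        if len(cands):
            return int(cands["day"].iloc[0]), tier
    raise SchedulingError(
        f"no suitable burn day for fire in cell ({row}, {col}), even with "
        "relaxed criteria"
    )


def collapse_multiday(fires: pd.DataFrame) -> pd.DataFrame:
    """Merge multi-day single-cell events into one record.

    An event whose records all lie in one grid cell collapses to a
    single record on its first day with the summed area. Events spanning
    several cells are left as independent per-cell records. Adds a
    boolean ``collapsed`` column.
    """
    if fires.empty:
        out = fires.copy()
        out["collapsed"] = pd.Series(dtype=bool)
        return out
    rows = []
    for event_id, grp in fires.groupby("event_id", sort=True):
        cells = grp[["row", "col"]].drop_duplicates()
        if len(cells) == 1 and len(grp) > 1:
            first = grp.sort_values("day").iloc[0]
            rec = first.to_dict()
            rec["area_km2"] = float(grp["area_km2"].sum())
            rec["collapsed"] = True
            rows.append(rec)
        else:
            for _, r in grp.iterrows():
                rec = r.to_dict()
                rec["collapsed"] = False
                rows.append(rec)
    out = pd.DataFrame(rows).reset_index(drop=True)
    int_cols = [c for c in ("event_id", "day", "row", "col", "fuelbed_id") if c in out]
    return out.astype({c: int for c in int_cols})


def build_scenario(
    fires: pd.DataFrame,
    met: xr.Dataset,
    criteria: BurnWindowCriteria = BurnWindowCriteria(),
    mode: str = "rx1",
    no_burn: NoBurnCalendar | None = None,
) -> pd.DataFrame:
    """Reassign every fire to a prescribed-burn day.

    mode 'rx1' ignores the no-burn calendar; 'rx2' removes its days
    before filtering. Returns the collapsed fire table with columns
    orig_day, day (assigned), tier and collapsed; total burned area is
    conserved exactly.
    """
    if mode not in ("rx1", "rx2"):
        raise ValueError(f"mode must be 'rx1' or 'rx2', got {mode!r}")
    cal = no_burn if mode == "rx2" else None
    merged = collapse_multiday(fires)
    if merged.empty:
        out = merged.copy()
        out["orig_day"] = pd.Series(dtype=int)
        out["tier"] = pd.Series(dtype=str)
        return out
    new_days = np.empty(len(merged), dtype=int)
    tiers = np.empty(len(merged), dtype=object)
    cache: dict[tuple[int, int], tuple[int, str]] = {}
    for i, f in enumerate(merged.itertuples()):
        key = (f.row, f.col)
        if key not in cache:
            cache[key] = assign_day(f.row, f.col, met, criteria, cal)
        new_days[i], tiers[i] = cache[key]
    out = merged.copy()
    out["orig_day"] = out["day"]
    out["day"] = new_days
    out["tier"] = tiers
    return out


def fallback_area_fraction(schedule: pd.DataFrame) -> float:
    """Fraction of total burned area placed via the fallback tier."""
    total = schedule["area_km2"].sum()
    if total == 0:
        return 0.0
    return float(schedule.loc[schedule["tier"] == "fallback", "area_km2"].sum() / total)


def screen_high_exposure_days(
    fires: pd.DataFrame,
    met: xr.Dataset,
    population: np.ndarray,
    grid: DomainGrid,
    surrogate_params=None,
    quantile: float = 0.9,
) -> NoBurnCalendar:
    """Build a no-burn calendar of high-population-exposure days.

    For every burn-season day, forecast the population-weighted PM2.5
    that would result if every pending fire released a unit emission in
    its cell on that day (single-day transport with that day's winds),
    then exclude days whose forecast exceeds the given quantile of the
    distribution over candidate days.
    """
    from .dispersion import SurrogateParams, disperse_single_day
    from .health import population_weighted

    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    if surrogate_params is None:
        surrogate_params = SurrogateParams()
    days = burn_season_days()
    emis = np.zeros((grid.n_rows, grid.n_cols))
    if len(fires):
        np.add.at(emis, (fires["row"].to_numpy(), fires["col"].to_numpy()), 1.0)
    if emis.sum() == 0 or quantile >= 1:
        return NoBurnCalendar(())
    pw = np.empty(len(days))
    for i, d in enumerate(days):
        conc = disperse_single_day(emis, met.sel(day=int(d)), grid, surrogate_params)
        pw[i] = population_weighted(conc, population)
    cut = np.quantile(pw, quantile)
    return NoBurnCalendar.from_days(days[pw > cut])
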