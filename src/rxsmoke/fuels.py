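"""Fuel-bed classification, consumption and species emissions.

Emissions follow the standard inventory product

    E_s = sum_FT  BA * FC_FT * EF_{s,FT}

with E_s the emitted mass of species s (g), BA the burned area (km^2),
FC_FT the fuel consumed per fuel type (kg/km^2), and EF the emission
factor (g/kg). Emission factors distinguish short-term flaming and
smoldering (STFS) by land-cover type — with separate western-forest
values for wildfire and prescribed (Rx) conditions — and residual
smoldering combustion (RSC) of woody debris and duff.

Consumption is a parameterized scheme: canopy consumption is 50% for
wildfires and 0% for prescribed burns, shrub blackening is 50% for both,
and the surface categories (nonwoody, woody, duff) burn a fraction that
decreases linearly with fuel moisture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

COVER_TYPES = ("forest", "shrubland", "grassland")
SURFACE_CATEGORIES = ("nonwoody", "woody", "duff")
FUEL_CATEGORIES = ("canopy", "shrub", "nonwoody", "woody", "duff")


class ClassificationError(ValueError):
    """Raised when a fuel bed cannot be assigned a cover type."""


class EmissionFactorError(KeyError):
    """Raised when no emission factor matches a lookup."""


def classify_fuelbed(loadings: dict[str, float] | pd.Series) -> str:
    """Assign a cover type from category loading shares.

    The comparison is between canopy+woody, shrub and nonwoody mass
    shares (duff does not enter): the largest share decides
    forest / shrubland / grassland respectively. Ties break by the
    precedence forest > shrubland > grassland.
    """
    vals = {c: float(loadings.get(c, 0.0)) for c in FUEL_CATEGORIES}
    if any(v < 0 for v in vals.values()):
        raise ClassificationError("negative fuel loading")
    shares = {
        "forest": vals["canopy"] + vals["woody"],
        "shrubland": vals["shrub"],
        "grassland": vals["nonwoody"],
    }
    total = sum(shares.values())
    if total <= 0:
        raise ClassificationError("all comparable loadings are zero")
    best = max(shares.values())
    for cover in COVER_TYPES:  # precedence order breaks ties
        if shares[cover] == best:
            return cover
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class ConsumptionParams:
    """Tunable consumption scheme.

    ``surface_frac_dry``/``surface_frac_wet`` are the consumed fractions
    of surface fuels at fuel moisture 0 and 1, interpolated linearly.
    ``woody_rsc_frac`` and ``duff_rsc_frac`` route the stated share of
    consumed woody and duff mass into residual smoldering combustion.
    """

    canopy_frac_wildfire: float = 0.50
    canopy_frac_rx: float = 0.0
    shrub_blackened_frac: float = 0.50
    surface_frac_dry: float = 0.9
    surface_frac_wet: float = 0.3
    woody_rsc_frac: float = 0.30
    duff_rsc_frac: float = 1.0
    fuel_moisture_min: float = 0.05
    fuel_moisture_max: float = 0.40


def fuel_moisture_from_soil(
    soil_moisture: float | np.ndarray, params: ConsumptionParams = ConsumptionParams()
) -> float | np.ndarray:
    """Map soil moisture (m3/m3 in [0,1]) onto a fuel-moisture fraction.

    Linear, monotone non-decreasing map onto
    [fuel_moisture_min, fuel_moisture_max].
    """
    sm = np.asarray(soil_moisture, dtype=float)
    if np.any((sm < 0) | (sm > 1)):
        raise ValueError("soil moisture outside [0, 1]")
    fm = params.fuel_moisture_min + sm * (params.fuel_moisture_max - params.fuel_moisture_min)
    return float(fm) if np.isscalar(soil_moisture) else fm


@dataclass
class ConsumptionResult:
    """Consumed fuel per category (kg/km^2), split into combustion phases.

    ``stfs`` is the flaming + short-term smoldering consumption per
    category; ``rsc`` the residual-smoldering share (only woody and duff
    are non-zero there). ``stfs[c] + rsc[c]`` is the category total.
    """

    stfs: dict[str, float]
    rsc: dict[str, float]
    cover_type: str

    @property
    def total_stfs(self) -> float:
        return sum(self.stfs.values())

    @property
    def total_rsc(self) -> float:
        return sum(self.rsc.values())

    @property
    def total(self) -> float:
        return self.total_stfs + self.total_rsc


def consume(
    loadings: dict[str, float] | pd.Series,
    fuel_moisture: float,
    fire_type: str,
    params: ConsumptionParams = ConsumptionParams(),
) -> ConsumptionResult:
    """Fuel consumed per category under wildfire or prescribed conditions.

    fire_type is 'wildfire' or 'rx'. Consumption never exceeds loading;
    surface consumption decreases linearly in fuel moisture.
    """
    if fire_type not in ("wildfire", "rx"):
        raise ValueError(f"fire_type must be 'wildfire' or 'rx', got {fire_type!r}")
    if not 0 <= fuel_moisture <= 1:
        raise ValueError("fuel_moisture outside [0, 1]")
    cover = classify_fuelbed(loadings)
    vals = {c: float(loadings.get(c, 0.0)) for c in FUEL_CATEGORIES}
    canopy_frac = (
        params.canopy_frac_wildfire if fire_type == "wildfire" else params.canopy_frac_rx
    )
    surf_frac = params.surface_frac_dry + fuel_moisture * (
        params.surface_frac_wet - params.surface_frac_dry
    )
    consumed = {
        "canopy": canopy_frac * vals["canopy"],
        "shrub": params.shrub_blackened_frac * vals["shrub"],
        "nonwoody": surf_frac * vals["nonwoody"],
        "woody": surf_frac * vals["woody"],
        "duff": surf_frac * vals["duff"],
    }
    rsc = {c: 0.0 for c in FUEL_CATEGORIES}
    rsc["woody"] = params.woody_rsc_frac * consumed["woody"]
    rsc["duff"] = params.duff_rsc_frac * consumed["duff"]
    stfs = {c: consumed[c] - rsc[c] for c in FUEL_CATEGORIES}
    return ConsumptionResult(stfs=stfs, rsc=rsc, cover_type=cover)


class EmissionFactorTable:
    """Emission factors (g/kg) keyed by (category, fire_type, species).

    ``category`` is a land-cover type for STFS factors ('forest',
    'shrubland', 'grassland') or a smoldering class ('woody_rsc',
    'duff_rsc'). fire_type 'any' matches both fire types. The shipped
    default table holds the PM2.5 factors: forest Rx 17.57 / wildfire
    23.2, shrubland 7.06, grassland 8.51, woody RSC 33, duff RSC 35.3.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"category", "fire_type", "species", "ef_g_per_kg"}
        if not required.issubset(table.columns):
            raise ValueError(f"EF table needs columns {sorted(required)}")
        if (table["ef_g_per_kg"] <= 0).any():
            raise ValueError("emission factors must be positive")
        self._table = table.reset_index(drop=True)
        self._index = {
            (r.category, r.fire_type, r.species): float(r.ef_g_per_kg)
            for r in table.itertuples()
        }

    @classmethod
    def default(cls) -> "EmissionFactorTable":
        path = resources.files("rxsmoke.data") / "emission_factors.csv"
        with resources.as_file(path) as p:
            return cls(pd.read_csv(p))

    @classmethod
    def from_csv(cls, path) -> "EmissionFactorTable":
        return cls(pd.read_csv(path))

    @property
    def species(self) -> list[str]:
        return sorted(self._table["species"].unique())

    def lookup(self, category: str, fire_type: str, species: str) -> float:
        for ft in (fire_type, "any"):
            ef = self._index.get((category, ft, species))
            if ef is not None:
                return ef
        raise EmissionFactorError(
            f"no emission factor for ({category}, {fire_type}, {species})"
        )


def emissions(
    burned_area_km2: float,
    consumption: ConsumptionResult,
    ef_table: EmissionFactorTable,
    fire_type: str,
    species: str = "PM2.5",
) -> float:
    """Emitted mass (g) of one species for one fire-day record.

    STFS consumption uses the cover-type STFS factor (fire-type specific
    for forest); residual-smoldering woody and duff use the RSC factors.
    """
    if burned_area_km2 < 0:
        raise ValueError("burned area must be >= 0")
    ef_stfs = ef_table.lookup(consumption.cover_type, fire_type, species)
    mass = burned_area_km2 * consumption.total_stfs * ef_stfs
    if consumption.rsc["woody"] > 0:
        mass += (
            burned_area_km2
            * consumption.rsc["woody"]
            * ef_table.lookup("woody_rsc", fire_type, species)
        )
    if consumption.rsc["duff"] > 0:
        mass += (
            burned_area_km2
            * consumption.rsc["duff"]
            * ef_table.lookup("duff_rsc", fire_type, species)
        )
    return mass


def build_inventory(
    fires: pd.DataFrame,
    fuelbeds: pd.DataFrame,
    met,
    fire_type: str,
    ef_table: EmissionFactorTable | None = None,
    params: ConsumptionParams = ConsumptionParams(),
    species: str = "PM2.5",
) -> pd.DataFrame:
    """Per fire-day emission records for one scenario.

    ``fires`` has columns (event_id, day, row, col, area_km2, ...);
    ``fuelbeds`` is indexed by fuelbed_id with category loadings; ``met``
    is the meteorology Dataset (soil_moisture drives fuel moisture on the
    burn day). Returns records with consumption totals and emitted mass.
    """
    if ef_table is None:
        ef_table = EmissionFactorTable.default()
    beds = fuelbeds.set_index("fuelbed_id")
    sm_arr = met["soil_moisture"].values  # (day, row, col), day coord 1-based
    n_cols = sm_arr.shape[2]
    records = []
    for f in fires.itertuples():
        bed_id = f.fuelbed_id if "fuelbed_id" in fires.columns else f.row * n_cols + f.col
        bed = beds.loc[bed_id]
        sm = float(sm_arr[f.day - 1, f.row, f.col])
        fm = fuel_moisture_from_soil(min(max(sm, 0.0), 1.0), params)
        cons = consume(bed[list(FUEL_CATEGORIES)], fm, fire_type, params)
        mass = emissions(f.area_km2, cons, ef_table, fire_type, species)
        records.append(
            (f.event_id, f.day, f.row, f.col, f.area_km2, cons.cover_type,
             cons.total, f.area_km2 * cons.total, species, mass)
        )
    return pd.DataFrame(
        records,
        columns=[
            "event_id", "day", "row", "col", "area_km2", "cover_type",
            "consumption_kg_per_km2", "fuel_consumed_kg", "species", "mass_g",
        ],
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def percent_reduction(baseline: float, scenario: float) -> int | None:
    """Integer percent reduction vs baseline, rounded half-up.

    Returns None when the baseline is zero (undefined reduction).
    """
    if baseline == 0:
        return None
    return _round_half_up((baseline - scenario) / baseline * 100.0)


def summarize_inventory(
    inventories: dict[str, pd.DataFrame],
    baseline: str = "wildfire",
    emission_threshold_g: float = 1e6,
) -> dict:
    """Scenario totals, percent reductions and daily series.

    ``inventories`` maps scenario name -> record frame from
    build_inventory. Totals are reported in Tg; percent reductions are
    relative to ``baseline`` and rounded half-up to integers. Also counts
    days with total emissions above ``emission_threshold_g``
    (default 1 tonne).
    """
    out: dict = {"scenarios": {}, "reductions": {}, "daily": {}}
    for name, inv in inventories.items():
        daily = (
            inv.groupby("day")["mass_g"].sum()
            if len(inv)
            else pd.Series(dtype=float)
        )
        out["scenarios"][name] = {
            "burned_area_km2": float(inv["area_km2"].sum()) if len(inv) else 0.0,
            "fuel_consumption_Tg": float(inv["fuel_consumed_kg"].sum()) * 1e-9
            if len(inv)
            else 0.0,
            "emissions_Tg": float(inv["mass_g"].sum()) * 1e-12 if len(inv) else 0.0,
            "days_over_threshold": int((daily > emission_threshold_g).sum()),
        }
        out["daily"][name] = daily
    if baseline in out["scenarios"]:
        base = out["scenarios"][baseline]
        for name, s in out["scenarios"].items():
            if name == baseline:
                continue
            out["reductions"][name] = {
                "burned_area_km2": percent_reduction(
                    base["burned_area_km2"], s["burned_area_km2"]
                ),
                "fuel_consumption_Tg": percent_reduction(
                    base["fuel_consumption_Tg"], s["fuel_consumption_Tg"]
                ),
                "emissions_Tg": percent_reduction(
                    base["emissions_Tg"], s["emissions_Tg"]
                ),
            }
    return out
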