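"""End-to-end scenario runs and the scenario comparison report.

``run`` chains the stages: synthesize inputs -> build the wildfire
emission inventory -> re-schedule fires onto prescribed-burn days (Rx1,
and Rx2 with the high-exposure-day screen) -> disperse each scenario's
emissions -> compute population-weighted exposure and excess mortality.
Everything is deterministic in the configured seed. The no-fire scenario
is implicit: the transport surrogate is linear and emits nothing without
fires, so fire increments are with-fire minus zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import dispersion, fuels, health, scheduler, synthetic
from .grid import DomainGrid


@dataclass
class RunConfig:
    """Configuration of an end-to-end scenario comparison."""

    seed: int = 0
    n_rows: int = 20
    n_cols: int = 20
    cell_size_km: float = 12.0
    n_fires: int = 200
    scenarios: tuple[str, ...] = ("wildfire", "rx1", "rx2")
    screen_quantile: float = 0.9
    synthetic_overrides: dict = field(default_factory=dict)
    criteria: scheduler.BurnWindowCriteria = field(
        default_factory=scheduler.BurnWindowCriteria
    )
    health_params: health.HealthParams = field(default_factory=health.HealthParams)
    surrogate_overrides: dict = field(default_factory=dict)

    def grid(self) -> DomainGrid:
        return DomainGrid(self.n_rows, self.n_cols, self.cell_size_km)

    def synthetic_config(self) -> synthetic.SyntheticConfig:
        return synthetic.SyntheticConfig(
            seed=self.seed, n_fires=self.n_fires, **self.synthetic_overrides
        )


def run(config: RunConfig) -> dict:
    """Execute the configured scenarios; return the report bundle.

    The bundle holds the synthetic inputs, per-scenario fire tables,
    inventories, concentration fields, health summaries, the inventory
    summary with percent reductions, and the formatted comparison table.
    """
    grid = config.grid()
    syn = config.synthetic_config()
    met = synthetic.generate_meteorology(grid, syn)
    fires = synthetic.generate_fires(grid, syn)
    population = synthetic.generate_population(grid, syn)
    fuelbeds = synthetic.generate_fuelbeds(grid, syn)
    ef_table = fuels.EmissionFactorTable.default()

    fire_tables: dict[str, pd.DataFrame] = {}
    inventories: dict[str, pd.DataFrame] = {}
    schedules: dict[str, pd.DataFrame] = {}
    no_burn = None
    for name in config.scenarios:
        if name == "wildfire":
            fire_tables[name] = fires
            fire_type = "wildfire"
        elif name in ("rx1", "rx2"):
            if name == "rx2":
                no_burn = scheduler.screen_high_exposure_days(
                    fires, met, population, grid,
                    dispersion.SurrogateParams.for_fire_type(
                        "rx", **config.surrogate_overrides
                    ),
                    quantile=config.screen_quantile,
                )
            sched = scheduler.build_scenario(
                fires, met, config.criteria, mode=name, no_burn=no_burn
            )
            schedules[name] = sched
            fire_tables[name] = sched
            fire_type = "rx"
        elif name == "nofire":
            fire_tables[name] = fires.iloc[0:0]
            fire_type = "wildfire"
        else:
            raise ValueError(f"unknown scenario {name!r}")
        inventories[name] = fuels.build_inventory(
            fire_tables[name], fuelbeds, met, fire_type, ef_table
        )

    summary = fuels.summarize_inventory(inventories)

    conc: dict = {}
    health_daily: dict = {}
    health_annual: dict = {}
    for name, inv in inventories.items():
        fire_type = "wildfire" if name in ("wildfire", "nofire") else "rx"
        params = dispersion.SurrogateParams.for_fire_type(
            fire_type, **config.surrogate_overrides
        )
        emis = dispersion.gridded_emissions(inv, grid, days=met["day"].values)
        conc[name] = dispersion.disperse(emis, met, grid, params)
        daily = health.health_time_series(
            population, conc[name], params=config.health_params
        )
        health_daily[name] = daily
        health_annual[name] = health.annual_summary(daily)

    return {
        "config": config,
        "grid": grid,
        "met": met,
        "fires": fires,
        "population": population,
        "fuelbeds": fuelbeds,
        "schedules": schedules,
        "no_burn": no_burn,
        "inventories": inventories,
        "summary": summary,
        "concentrations": conc,
        "health_daily": health_daily,
        "health_annual": health_annual,
        "report": scenario_report(summary, health_annual),
    }


_ROW_LABELS = (
    ("burned_area_km2", "burned area (km2)", "{:,.0f}"),
    ("fuel_consumption_Tg", "fuel consumption (Tg)", "{:.3g}"),
    ("emissions_Tg", "PM2.5 (Tg)", "{:.3g}"),
)


def scenario_report(
    summary: dict, health_annual: dict | None = None, baseline: str = "wildfire"
) -> str:
    """Format the scenario comparison as a text table.

    Rows: burned area, fuel consumption, species emissions (plus excess
    deaths when health summaries are given). Non-baseline columns carry
    the integer percent reduction vs the baseline in brackets; an
    undefined reduction (zero baseline) prints (n/a).
    """
    scenarios = list(summary["scenarios"])
    lines = ["scenario comparison".ljust(26) + "".join(s.rjust(22) for s in scenarios)]
    for key, label, fmt in _ROW_LABELS:
        cells = []
        for name in scenarios:
            value = summary["scenarios"][name][key]
            text = fmt.format(value)
            if name != baseline and baseline in summary["scenarios"]:
                red = summary.get("reductions", {}).get(name, {}).get(key)
                text += " (n/a)" if red is None else f" ({red}%)"
            cells.append(text.rjust(22))
        lines.append(label.ljust(26) + "".join(cells))
    cells = [
        str(summary["scenarios"][name]["days_over_threshold"]).rjust(22)
        for name in scenarios
    ]
    lines.append("days > 1 t emissions".ljust(26) + "".join(cells))
    if health_annual:
        for key, label, fmt in (
            ("mean_pw_pm25", "annual mean PW (ug/m3)", "{:.3g}"),
            ("annual_deaths", "excess deaths", "{:.1f}"),
        ):
            cells = [
                fmt.format(health_annual[name][key]).rjust(22)
                for name in scenarios
                if name in health_annual
            ]
            lines.append(label.ljust(26) + "".join(cells))
    return "\n".join(lines)


def report_from_totals(
    totals: dict[str, dict[str, float]], baseline: str = "wildfire"
) -> str:
    """Comparison table from externally supplied scenario totals.

    ``totals`` maps scenario -> {burned_area_km2, fuel_consumption_Tg,
    emissions_Tg}; percent reductions are computed here, so published
    totals can be fed straight through.
    """
    summary: dict = {"scenarios": {}, "reductions": {}}
    for name, vals in totals.items():
        summary["scenarios"][name] = {
            "burned_area_km2": vals.get("burned_area_km2", 0.0),
            "fuel_consumption_Tg": vals.get("fuel_consumption_Tg", 0.0),
            "emissions_Tg": vals.get("emissions_Tg", 0.0),
            "days_over_threshold": vals.get("days_over_threshold", 0),
        }
    base = summary["scenarios"].get(baseline)
    if base:
        for name, s in summary["scenarios"].items():
            if name == baseline:
                continue
            summary["reductions"][name] = {
                key: fuels.percent_reduction(base[key], s[key])
                for key in ("burned_area_km2", "fuel_consumption_Tg", "emissions_Tg")
            }
    return scenario_report(summary, baseline=baseline)
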