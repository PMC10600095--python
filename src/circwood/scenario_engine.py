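"""Full scenario runs 2022-2050: Scope 1-4 assembly, comparisons,
delayed implementation and afforestation combination.

Sign convention throughout: emissions positive, removals and avoided
emissions negative; a "reduction" is the magnitude of a negative net.

The net Scope 1-3 series is the sum of the process-emission components plus
the signed change in domestic HWP carbon storage (a UK-attributed biogenic
term); the net Scope 1-4 series adds the avoided-emission components
(substitution, reduced harvest, import changes). Biogenic storage and
avoided-harvest credits are constant annualised values from the
implementation year onward (50-year window for HWP, study-period window for
the forest), as year-resolved pool series would double-count the
annualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import forest_carbon, hwp_carbon, substitution as subst, wood_flow
from .emissions_engine import (
    SCOPE4_COMPONENTS,
    DecarbSchedule,
    EmissionFactorInventory,
    component_process_emissions,
    import_delta_emissions,
)
from .forest_carbon import (
    AfforestationProgramme,
    EstateConfig,
    YieldCurve,
    afforestation_series,
    avoided_harvest_credit,
)
from .hwp_carbon import CarbonConvention, stock_series, storage_change_credit
from .substitution import (
    SubstitutionSpec,
    construction_substitution_credit,
    fuel_substitution_credit,
)
from .wood_flow import FlowTable, derive_import_deltas, scale_to_harvest

__all__ = [
    "InputBundle",
    "ScenarioConfig",
    "ScenarioResult",
    "run_scenario",
    "run_all_scenarios",
    "compare_scenarios",
    "run_afforestation",
    "combine_with_afforestation",
]


@dataclass
class InputBundle:
    """Everything one simulation needs, in memory.

    ``flow_tables`` hold the four scenarios at any common normalisation (the
    engine rescales them to ``harvest``). ``woodfuel_import_replacement_fraction``
    is the imported woodfuel replacing diverted recycled-waste-MDF fuel in
    circular scenarios, as a fraction of the harvest.
    """

    flow_tables: dict[str, FlowTable]
    inventory: EmissionFactorInventory
    schedule: DecarbSchedule
    half_lives: dict[str, float]
    convention: CarbonConvention
    substitution: SubstitutionSpec
    estate: EstateConfig
    estate_curve: YieldCurve
    afforestation_curves: dict[str, YieldCurve]
    harvest: float = 9.5e6
    woodfuel_import_replacement_fraction: float = 0.0


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario run: which flow table, when it replaces BAU, horizons.

    Study year 1 is the year after ``start_year``; "implement in year N"
    therefore maps to calendar start_year + N (default: year 5 = 2027).
    """

    scenario_id: str
    start_year: int = 2022
    end_year: int = 2050
    implementation_year: int = 2027
    hwp_window: int = 50
    forest_window: int = 28

    def __post_init__(self):
        if not self.start_year <= self.implementation_year <= self.end_year:
            raise ValueError(
                "implementation_year must lie within [start_year, end_year]"
            )

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1))


@dataclass
class ScenarioResult:
    """Year x component x scope emission table plus derived net series."""

    scenario_id: str
    config: ScenarioConfig
    data: pd.DataFrame  # columns: year, component, scope, value_tco2e

    def component_table(self) -> pd.DataFrame:
        return self.data.pivot_table(
            index="year", columns=["component", "scope"],
            values="value_tco2e", aggfunc="sum", fill_value=0.0,
        )

    def net_s13(self) -> pd.Series:
        """Annual net Scope 1-3 (t CO2e): process emissions plus the signed
        change in UK HWP carbon storage."""
        mask = (self.data["scope"].isin([1, 2, 3])) | (
            self.data["component"] == "change_in_uk_hwp_c_storage"
        )
        return self.data[mask].groupby("year")["value_tco2e"].sum()

    def net_s14(self) -> pd.Series:
        """Annual net Scope 1-4 (t CO2e): everything, signed."""
        return self.data.groupby("year")["value_tco2e"].sum()

    def cumulative_net_s14(self) -> pd.Series:
        return self.net_s14().cumsum()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def summary(self) -> dict:
        net14 = self.net_s14()
        return {
            "scenario_id": self.scenario_id,
            "implementation_year": self.config.implementation_year,
            "net_s13_final_tco2e": float(self.net_s13().iloc[-1]),
            "net_s14_final_tco2e": float(net14.iloc[-1]),
            "cumulative_net_s14_tco2e": float(net14.sum()),
        }


def _active_table(bundle: InputBundle, config: ScenarioConfig, year: int) -> FlowTable:
    if config.scenario_id != "bau" and year >= config.implementation_year:
        return bundle.flow_tables[config.scenario_id]
    return bundle.flow_tables["bau"]


def _woodfuel_replacement(bundle: InputBundle, table: FlowTable) -> float:
    """Imported-woodfuel volume (green t/yr) replacing diverted waste-MDF
    fuel; only circular scenarios (positive recycled-MDF production) get it."""
    if table.production("recycled_mdf") > 0:
        return bundle.woodfuel_import_replacement_fraction * bundle.harvest
    return 0.0


def _production_tc(
    table: FlowTable, convention: CarbonConvention
) -> dict[str, float]:
    return {
        cat: convention.green_tonnes_to_c(table.production(cat))
        for cat in wood_flow.HWP_CATEGORIES
    }


def _hwp_credit(
    bundle: InputBundle, config: ScenarioConfig, scenario: FlowTable, bau: FlowTable
) -> float:
    """Annualised HWP storage credit versus BAU over the 50-year window.

    Production is constant within each regime and held at its final value
    past the horizon, so the window sees a step change at implementation.
    """
    window_years = list(range(config.implementation_year,
                              config.implementation_year + config.hwp_window))
    scen_prod = pd.DataFrame(
        {c: v for c, v in _production_tc(scenario, bundle.convention).items()},
        index=pd.Index(window_years, name="year"),
    )
    bau_prod = pd.DataFrame(
        {c: v for c, v in _production_tc(bau, bundle.convention).items()},
        index=pd.Index(window_years, name="year"),
    )
    scen_series = stock_series(scen_prod, bundle.half_lives)
    bau_series = stock_series(bau_prod, bundle.half_lives)
    return storage_change_credit(scen_series, bau_series, window=config.hwp_window)


def run_scenario(bundle: InputBundle, config: ScenarioConfig) -> ScenarioResult:
    """Simulate one scenario over the study period.

    Before the implementation year every scenario runs on the BAU flows, so
    the BAU run carries zero HWP-change, import-change and avoided-harvest
    entries by construction.
    """
    if config.scenario_id not in bundle.flow_tables:
        raise KeyError(f"unknown scenario {config.scenario_id!r}")
    tables = {
        sid: scale_to_harvest(t, bundle.harvest)
        for sid, t in bundle.flow_tables.items()
    }
    scaled = replace(bundle, flow_tables=tables)
    bau = tables["bau"]
    scenario_table = tables[config.scenario_id]

    # constant annualised credits, applied from the implementation year
    hwp_credit = 0.0
    harvest_credit = 0.0
    if config.scenario_id != "bau":
        hwp_credit = _hwp_credit(scaled, config, scenario_table, bau)
        harvest_credit, _ = avoided_harvest_credit(
            scenario_table.production("recycled_mdf"),
            scaled.estate_curve,
            scaled.estate,
            window=config.forest_window,
        )

    rows = []
    for year in config.years:
        active = _active_table(scaled, config, year)
        implemented = active is not bau

        proc = component_process_emissions(
            active, scaled.inventory, year, scaled.schedule
        )
        for r in proc.itertuples():
            rows.append((year, r.component, int(r.scope), float(r.value_tco2e)))

        replacement = _woodfuel_replacement(scaled, active) if implemented else 0.0
        deltas = derive_import_deltas(active, bau, replacement)
        imp = import_delta_emissions(deltas, scaled.inventory, year, scaled.schedule)
        rows.append(
            (year, "change_in_import_emissions", 4,
             float(imp["value_tco2e"].iloc[0]))
        )

        rows.append((year, "change_in_uk_hwp_c_storage", 4,
                     hwp_credit if implemented else 0.0))
        rows.append((year, "avoided_reduced_harvest", 4,
                     harvest_credit if implemented else 0.0))

        # substitution: national consumption is constant, so construction
        # timber is the BAU carcassing supply; woodfuel is the active
        # domestic production plus the configured import replacement
        wood_fuel = active.production("woodfuel") + replacement
        fuel_credit = fuel_substitution_credit(
            wood_fuel, scaled.substitution, year, scaled.schedule
        )
        carc_green = bau.production("carcassing")
        mass_20mc = (
            carc_green * (1.0 - scaled.convention.moisture_green) / (1.0 - 0.20)
        )
        constr_credit = construction_substitution_credit(
            mass_20mc, scaled.substitution, year, scaled.schedule
        )
        rows.append((year, "avoided_product_substitution", 4,
                     fuel_credit + constr_credit))

    data = pd.DataFrame(rows, columns=["year", "component", "scope", "value_tco2e"])
    return ScenarioResult(scenario_id=config.scenario_id, config=config, data=data)


def run_all_scenarios(
    bundle: InputBundle, config: ScenarioConfig | None = None
) -> dict[str, ScenarioResult]:
    """Run every scenario in the bundle under a shared configuration."""
    base = config or ScenarioConfig(scenario_id="bau")
    return {
        sid: run_scenario(bundle, replace(base, scenario_id=sid))
        for sid in bundle.flow_tables
    }


def compare_scenarios(
    a: ScenarioResult, b: ScenarioResult, metric: str, year: int | None = None
) -> float:
    """Percentage comparison of two runs.

    * ``s13_pct_lower``: how much lower b's net Scope 1-3 is than a's at
      ``year``: (S13_a - S13_b) / S13_a x 100.
    * ``s14_pct_larger_reduction``: how much larger b's net Scope 1-4
      reduction is than a's at ``year`` (both nets must be negative):
      (|net14_b| - |net14_a|) / |net14_a| x 100.
    * ``cumulative_pct_larger``: the same on cumulative net Scope 1-4 at the
      final year.

    Raises ``ValueError`` (never returns NaN) when the reference is zero, or
    positive where a reduction is required.
    """
    if metric == "s13_pct_lower":
        if year is None:
            raise ValueError("year required for s13_pct_lower")
        ref = float(a.net_s13().loc[year])
        val = float(b.net_s13().loc[year])
        if ref == 0.0:
            raise ValueError("reference net Scope 1-3 is zero; % undefined")
        return (ref - val) / ref * 100.0
    if metric in ("s14_pct_larger_reduction", "cumulative_pct_larger"):
        if metric == "cumulative_pct_larger":
            ref = float(a.cumulative_net_s14().iloc[-1])
            val = float(b.cumulative_net_s14().iloc[-1])
        else:
            if year is None:
                raise ValueError("year required for s14_pct_larger_reduction")
            ref = float(a.net_s14().loc[year])
            val = float(b.net_s14().loc[year])
        if ref >= 0.0 or val >= 0.0:
            raise ValueError(
                "reduction comparison requires negative nets; got "
                f"{ref:g} and {val:g}"
            )
        return (abs(val) - abs(ref)) / abs(ref) * 100.0
    raise ValueError(f"unknown metric {metric!r}")


def run_afforestation(
    bundle: InputBundle,
    planting_rate_ha: float = 20_000.0,
    start_year: int = 2023,
    end_year: int = 2050,
    mix: tuple[tuple[float, str], ...] = (
        (0.5, "sitka_spruce"),
        (0.5, "conifer_broadleaf_mix"),
    ),
    years: list[int] | None = None,
) -> pd.DataFrame:
    """National afforestation programme series (annual + cumulative t CO2e).

    Default: 20,000 ha/yr from 2023 to 2050, half commercial conifer and
    half a 50:50 conifer:broadleaf mix; no harvest within the horizon.
    """
    prog = AfforestationProgramme(
        planting_rate_ha=planting_rate_ha,
        start_year=start_year,
        end_year=end_year,
        mix=tuple(
            (frac, name, bundle.afforestation_curves[name]) for frac, name in mix
        ),
    )
    years = years or list(range(2022, end_year + 1))
    return afforestation_series(prog, years)


def combine_with_afforestation(
    result: ScenarioResult, afforest: pd.DataFrame
) -> pd.DataFrame:
    """Combined cumulative net Scope 1-4: scenario + programme, additive
    (no interaction is modelled)."""
    cum = result.cumulative_net_s14()
    combined = cum.add(afforest["cumulative_tco2e"], fill_value=0.0)
    return pd.DataFrame(
        {
            "scenario_cumulative_tco2e": cum,
            "afforestation_cumulative_tco2e": afforest["cumulative_tco2e"],
            "combined_cumulative_tco2e": combined,
        }
    )
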