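"""Self-contained input generation.

Two generators:

* :func:`make_calibrated_fixture` -- a deterministic input bundle whose
  structure echoes the national case study the model is built around: four
  mass-balanced wood-flow scenarios normalised to a harvest of 100 (scaled
  to 9.5 million green tonnes/yr at run time), an emission-factor inventory
  whose BAU Scope 1-3 burden is dominated by wood-panel production (~63%)
  with a large resin (Scope 3) share (~40% of the panel burden), fuel and
  construction substitution credits of similar magnitude, a decadal
  decarbonisation schedule, product half-lives and parametric yield curves.
  All magnitudes are calibration choices, not measured data.

* :func:`random_instance` -- a seeded pseudo-random bundle (balanced flows
  by construction, log-uniform factors, random half-lives and yield classes)
  for property-based testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .emissions_engine import DecarbSchedule, EmissionFactor, EmissionFactorInventory
from .forest_carbon import EstateConfig, YieldCurve
from .hwp_carbon import DEFAULT_HALF_LIVES, CarbonConvention
from .scenario_engine import InputBundle
from .substitution import SubstitutionSpec
from .wood_flow import HWP_CATEGORIES, FlowTable, build_scenario_flows

__all__ = ["SyntheticSpec", "make_calibrated_fixture", "random_instance"]


# ---------------------------------------------------------------------------
# Deterministic calibrated fixture
# ---------------------------------------------------------------------------

# Flow specs normalised to a forest-gate harvest of 100 green tonnes/yr.
# Shares are calibration: they reproduce the qualitative scenario structure
# (BAU cascades recovered waste wood into particleboard and energy; cascading
# raises carcassing output; circular recycles waste MDF and diverts spared
# virgin wood to sawmills) without claiming the case study's exact volumes.
_FIXTURE_FLOWS: dict[str, list[tuple[str, str, float]]] = {
    "bau": [
        ("forest_gate", "sawmill", 55.0),
        ("forest_gate", "panel_mill", 30.0),
        ("forest_gate", "woodfuel_plant", 10.0),
        ("forest_gate", "other", 5.0),
        ("sawmill", "carcassing", 20.0),
        ("sawmill", "fencing", 8.0),
        ("sawmill", "fence_poles", 3.0),
        ("sawmill", "packaging_pallets", 7.0),
        ("sawmill", "panel_mill", 12.0),
        ("sawmill", "woodfuel_plant", 5.0),
        ("waste_wood", "panel_mill", 8.0),
        ("waste_wood", "woodfuel_plant", 7.0),
        ("panel_mill", "particleboard", 28.0),
        ("panel_mill", "mdf", 20.0),
        ("panel_mill", "loss", 2.0),
        ("woodfuel_plant", "woodfuel", 22.0),
    ],
    "cascading": [
        ("forest_gate", "sawmill", 70.0),
        ("forest_gate", "panel_mill", 17.0),
        ("forest_gate", "woodfuel_plant", 8.0),
        ("forest_gate", "other", 5.0),
        ("sawmill", "carcassing", 30.0),
        ("sawmill", "fencing", 8.0),
        ("sawmill", "fence_poles", 3.0),
        ("sawmill", "packaging_pallets", 7.0),
        ("sawmill", "panel_mill", 15.0),
        ("sawmill", "woodfuel_plant", 7.0),
        ("waste_wood", "panel_mill", 8.0),
        ("waste_wood", "woodfuel_plant", 7.0),
        ("panel_mill", "particleboard", 24.0),
        ("panel_mill", "mdf", 14.0),
        ("panel_mill", "loss", 2.0),
        ("woodfuel_plant", "woodfuel", 22.0),
    ],
    "circular": [
        ("forest_gate", "sawmill", 62.0),
        ("forest_gate", "panel_mill", 23.0),
        ("forest_gate", "woodfuel_plant", 10.0),
        ("forest_gate", "other", 5.0),
        ("sawmill", "carcassing", 22.0),
        ("sawmill", "fencing", 9.0),
        ("sawmill", "fence_poles", 3.0),
        ("sawmill", "packaging_pallets", 8.0),
        ("sawmill", "panel_mill", 13.0),
        ("sawmill", "woodfuel_plant", 7.0),
        ("waste_wood", "panel_mill", 8.0),
        ("waste_wood", "mdf_recycling", 6.0),
        ("waste_wood", "woodfuel_plant", 1.0),
        ("mdf_recycling", "recycled_mdf", 6.0),
        ("panel_mill", "particleboard", 26.0),
        ("panel_mill", "mdf", 16.0),
        ("panel_mill", "loss", 2.0),
        ("woodfuel_plant", "woodfuel", 18.0),
    ],
    "cascading_circular": [
        ("forest_gate", "sawmill", 72.0),
        ("forest_gate", "panel_mill", 13.0),
        ("forest_gate", "woodfuel_plant", 10.0),
        ("forest_gate", "other", 5.0),
        ("sawmill", "carcassing", 30.0),
        ("sawmill", "fencing", 9.0),
        ("sawmill", "fence_poles", 3.0),
        ("sawmill", "packaging_pallets", 8.0),
        ("sawmill", "panel_mill", 15.0),
        ("sawmill", "woodfuel_plant", 7.0),
        ("waste_wood", "panel_mill", 8.0),
        ("waste_wood", "mdf_recycling", 6.0),
        ("waste_wood", "woodfuel_plant", 1.0),
        ("mdf_recycling", "recycled_mdf", 6.0),
        ("panel_mill", "particleboard", 22.0),
        ("panel_mill", "mdf", 12.0),
        ("panel_mill", "loss", 2.0),
        ("woodfuel_plant", "woodfuel", 18.0),
    ],
}

# kg CO2e per green tonne of node throughput. Panel factors are set so wood
# panels carry ~63% of the BAU Scope 1-3 burden and resin (the scope-3
# chemicals row) ~40% of the panel burden; recycled-MDF production is less
# energy-intensive than virgin MDF.
_FIXTURE_FACTORS: list[tuple[str, int, float, str]] = [
    ("forest_gate", 1, 8.0, "fossil_fuel"),
    ("forest_gate", 2, 1.0, "electricity"),
    ("forest_gate", 3, 3.0, "chemicals"),
    ("sawmill", 1, 6.0, "fossil_fuel"),
    ("sawmill", 2, 8.0, "electricity"),
    ("sawmill", 3, 2.0, "chemicals"),
    ("panel_mill", 1, 25.0, "fossil_fuel"),
    ("panel_mill", 2, 20.6, "electricity"),
    ("panel_mill", 3, 30.4, "chemicals"),  # resin
    ("mdf_recycling", 1, 10.0, "fossil_fuel"),
    ("mdf_recycling", 2, 12.0, "electricity"),
    ("mdf_recycling", 3, 8.0, "chemicals"),  # resin
    ("woodfuel_plant", 1, 4.0, "fossil_fuel"),
    ("woodfuel_plant", 2, 2.0, "electricity"),
    ("woodfuel_plant", 3, 1.0, "chemicals"),
    # Import processing, per green tonne of product, equal per unit product
    # to the domestic chain (sawn ~23, panels ~79, fuel ~7 kg CO2e/t).
    ("import_processing_carcassing", 1, 10.0, "fossil_fuel"),
    ("import_processing_carcassing", 2, 10.0, "electricity"),
    ("import_processing_carcassing", 3, 3.0, "chemicals"),
    ("import_processing_fencing", 1, 10.0, "fossil_fuel"),
    ("import_processing_fencing", 2, 10.0, "electricity"),
    ("import_processing_fencing", 3, 3.0, "chemicals"),
    ("import_processing_fence_poles", 1, 10.0, "fossil_fuel"),
    ("import_processing_fence_poles", 2, 10.0, "electricity"),
    ("import_processing_fence_poles", 3, 3.0, "chemicals"),
    ("import_processing_packaging_pallets", 1, 10.0, "fossil_fuel"),
    ("import_processing_packaging_pallets", 2, 10.0, "electricity"),
    ("import_processing_packaging_pallets", 3, 3.0, "chemicals"),
    ("import_processing_other", 1, 10.0, "fossil_fuel"),
    ("import_processing_other", 2, 10.0, "electricity"),
    ("import_processing_other", 3, 3.0, "chemicals"),
    ("import_processing_particleboard", 1, 30.0, "fossil_fuel"),
    ("import_processing_particleboard", 2, 19.0, "electricity"),
    ("import_processing_particleboard", 3, 30.0, "chemicals"),
    ("import_processing_mdf", 1, 30.0, "fossil_fuel"),
    ("import_processing_mdf", 2, 19.0, "electricity"),
    ("import_processing_mdf", 3, 30.0, "chemicals"),
    ("import_processing_recycled_mdf", 1, 30.0, "fossil_fuel"),
    ("import_processing_recycled_mdf", 2, 19.0, "electricity"),
    ("import_processing_recycled_mdf", 3, 30.0, "chemicals"),
    ("import_processing_woodfuel", 1, 5.0, "fossil_fuel"),
    ("import_processing_woodfuel", 2, 2.0, "electricity"),
    ("import_transport", 3, 25.0, "transport"),
]

# Decadal multipliers (calibration; electricity decarbonises fastest, a
# residual remains at 2050 -- full decarbonisation lies beyond the horizon).
_FIXTURE_SCHEDULE: dict[str, dict[int, float]] = {
    "fossil_fuel": {2030: 0.65, 2040: 0.35, 2050: 0.10},
    "electricity": {2030: 0.50, 2040: 0.20, 2050: 0.05},
    "chemicals": {2030: 0.70, 2040: 0.40, 2050: 0.15},
    "transport": {2030: 0.70, 2040: 0.40, 2050: 0.15},
    "energy_supply": {2030: 0.60, 2040: 0.30, 2050: 0.10},
    "minerals": {2030: 0.70, 2040: 0.40, 2050: 0.15},
}


def _sitka_curve() -> YieldCurve:
    # ~YC16 Sitka spruce: V(50) ~ 800 m3/ha
    return YieldCurve.from_chapman_richards(
        "sitka_spruce", 16.0, asymptote=1100.0, rate=0.045, shape=2.8
    )


def _mixed_curve() -> YieldCurve:
    # 50:50 conifer:broadleaf mix, aggregate yield class ~9
    return YieldCurve.from_chapman_richards(
        "conifer_broadleaf_mix", 9.0, asymptote=700.0, rate=0.040, shape=3.0
    )


def make_calibrated_fixture(harvest: float = 9.5e6) -> InputBundle:
    """Deterministic input bundle echoing the national case-study structure.

    Flows are normalised to 100 and scaled to ``harvest`` by the scenario
    engine. Regenerating the fixture always yields identical values.
    """
    tables = {
        sid: build_scenario_flows(spec, scenario_id=sid)
        for sid, spec in _FIXTURE_FLOWS.items()
    }
    inventory = EmissionFactorInventory(
        EmissionFactor(p, s, v, "green_tonne", sector)
        for p, s, v, sector in _FIXTURE_FACTORS
    )
    schedule = DecarbSchedule(_FIXTURE_SCHEDULE)
    return InputBundle(
        flow_tables=tables,
        inventory=inventory,
        schedule=schedule,
        half_lives=dict(DEFAULT_HALF_LIVES),
        convention=CarbonConvention(),
        substitution=SubstitutionSpec(),
        estate=EstateConfig(),
        estate_curve=_sitka_curve(),
        afforestation_curves={
            "sitka_spruce": _sitka_curve(),
            "conifer_broadleaf_mix": _mixed_curve(),
        },
        harvest=harvest,
        # imported woodfuel replacing one normalised unit of the diverted
        # recycled-waste-MDF fuel, leaving a real net consumption reduction
        woodfuel_import_replacement_fraction=0.01,
    )


# ---------------------------------------------------------------------------
# Seeded random instances for property tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    """Targets for random instance generation (shares in (0, 1))."""

    seed: int
    harvest: float = 9.5e6
    recycled_mdf_fraction: float = 0.06  # of harvest, circular scenarios

    def __post_init__(self):
        if not 0.0 < self.recycled_mdf_fraction < 1.0:
            raise ValueError("recycled_mdf_fraction must lie in (0, 1)")


def _random_tables(rng: np.random.Generator, rmdf: float) -> dict[str, FlowTable]:
    """Four balanced flow tables with randomised shares.

    The BAU topology is randomised; cascading shifts panel wood to sawmills,
    circular adds the waste-MDF recycling edge with diversion of virgin wood
    away from panels. Balance holds by construction.
    """
    tables = {}
    for sid in ("bau", "cascading", "circular", "cascading_circular"):
        cascade = sid in ("cascading", "cascading_circular")
        circular = sid in ("circular", "cascading_circular")
        shares = rng.dirichlet([8.0, 4.0, 1.5, 0.8]) * 100.0
        saw, panel, fuel, other = shares
        if cascade:
            shift = 0.3 * panel
            saw, panel = saw + shift, panel - shift
        if circular:
            divert = 0.2 * panel
            saw, panel = saw + divert, panel - divert
        # sawmill outputs: products, residues to panel mill and woodfuel
        out = rng.dirichlet([5.0, 2.0, 1.0, 2.0, 3.0, 1.5]) * saw
        carc, fenc, poles, pack, to_panel, to_fuel = out
        waste_total = 15.0
        rec = rmdf * 100.0 if circular else 0.0
        waste_to_panel = 0.55 * (waste_total - rec)
        waste_to_fuel = waste_total - rec - waste_to_panel
        panel_in = panel + to_panel + waste_to_panel
        loss = 0.05 * panel_in
        pb_share = rng.uniform(0.5, 0.65)
        pb = pb_share * (panel_in - loss)
        mdf = panel_in - loss - pb
        fuel_in = fuel + to_fuel + waste_to_fuel
        spec = [
            ("forest_gate", "sawmill", saw),
            ("forest_gate", "panel_mill", panel),
            ("forest_gate", "woodfuel_plant", fuel),
            ("forest_gate", "other", other),
            ("sawmill", "carcassing", carc),
            ("sawmill", "fencing", fenc),
            ("sawmill", "fence_poles", poles),
            ("sawmill", "packaging_pallets", pack),
            ("sawmill", "panel_mill", to_panel),
            ("sawmill", "woodfuel_plant", to_fuel),
            ("waste_wood", "panel_mill", waste_to_panel),
            ("waste_wood", "woodfuel_plant", waste_to_fuel),
            ("panel_mill", "particleboard", pb),
            ("panel_mill", "mdf", mdf),
            ("panel_mill", "loss", loss),
            ("woodfuel_plant", "woodfuel", fuel_in),
        ]
        if circular:
            spec += [
                ("waste_wood", "mdf_recycling", rec),
                ("mdf_recycling", "recycled_mdf", rec),
            ]
        tables[sid] = build_scenario_flows(spec, scenario_id=sid)
    return tables


def random_instance(spec: SyntheticSpec) -> InputBundle:
    """Seeded pseudo-random input bundle; a pure function of the seed."""
    rng = np.random.default_rng(spec.seed)
    tables = _random_tables(rng, spec.recycled_mdf_fraction)

    processes = [
        "forest_gate", "sawmill", "panel_mill", "mdf_recycling", "woodfuel_plant",
    ]
    sectors = ["fossil_fuel", "electricity", "chemicals"]
    factors = []
    for p in processes:
        for scope, sector in zip((1, 2, 3), sectors):
            value = float(np.exp(rng.uniform(np.log(0.5), np.log(50.0))))
            factors.append(EmissionFactor(p, scope, value, "green_tonne", sector))
    for cat in HWP_CATEGORIES:
        value = float(np.exp(rng.uniform(np.log(1.0), np.log(80.0))))
        factors.append(
            EmissionFactor(
                f"import_processing_{cat}", 1, value, "green_tonne", "fossil_fuel"
            )
        )
    factors.append(
        EmissionFactor("import_transport", 3,
                       float(rng.uniform(5.0, 50.0)), "green_tonne", "transport")
    )
    inventory = EmissionFactorInventory(factors)

    schedule_sectors = sectors + ["transport", "energy_supply", "minerals"]
    steps = {}
    for s in schedule_sectors:
        m1 = float(rng.uniform(0.4, 0.9))
        m2 = float(rng.uniform(0.1, m1))
        m3 = float(rng.uniform(0.0, m2))
        steps[s] = {2030: m1, 2040: m2, 2050: m3}
    schedule = DecarbSchedule(steps)

    half_lives = {
        cat: (0.0 if cat == "woodfuel" else float(rng.uniform(2.0, 50.0)))
        for cat in HWP_CATEGORIES
    }
    yc = float(rng.uniform(8.0, 24.0))
    curve = YieldCurve.from_chapman_richards(
        "random_conifer", yc,
        asymptote=float(rng.uniform(600.0, 1400.0)),
        rate=float(rng.uniform(0.03, 0.06)),
        shape=float(rng.uniform(2.0, 3.5)),
    )
    return InputBundle(
        flow_tables=tables,
        inventory=inventory,
        schedule=schedule,
        half_lives=half_lives,
        convention=CarbonConvention(),
        substitution=SubstitutionSpec(),
        estate=EstateConfig(),
        estate_curve=curve,
        afforestation_curves={"random_conifer": curve},
        harvest=spec.harvest,
        woodfuel_import_replacement_fraction=float(rng.uniform(0.0, 0.01)),
    )
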