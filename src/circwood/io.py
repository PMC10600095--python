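"""Reading and writing the declarative input formats.

A run directory holds plain CSV inputs plus a single YAML run configuration
(``run.yaml``) naming them and carrying the scalar blocks (estate,
conversion convention, substitution constants, run years). The synthetic
generators write this layout; the CLI consumes it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .emissions_engine import DecarbSchedule, EmissionFactorInventory
from .forest_carbon import EstateConfig, YieldCurve
from .hwp_carbon import CarbonConvention, half_lives_from_csv, half_lives_to_csv
from .scenario_engine import InputBundle, ScenarioConfig
from .substitution import SubstitutionSpec
from .wood_flow import FlowTable

__all__ = ["write_bundle", "load_bundle", "load_run_config"]


def _curves_to_frame(curves: dict[str, YieldCurve]) -> pd.DataFrame:
    rows = []
    for curve in curves.values():
        for age, vol in zip(curve.ages, curve.volumes):
            rows.append(
                {
                    "species": curve.species,
                    "yield_class": curve.yield_class,
                    "age": age,
                    "volume_m3_ha": vol,
                }
            )
    return pd.DataFrame(rows)


def _curves_from_frame(df: pd.DataFrame) -> dict[str, YieldCurve]:
    curves = {}
    for species, grp in df.groupby("species"):
        grp = grp.sort_values("age")
        curves[str(species)] = YieldCurve(
            species=str(species),
            yield_class=float(grp["yield_class"].iloc[0]),
            ages=tuple(grp["age"].astype(float)),
            volumes=tuple(grp["volume_m3_ha"].astype(float)),
        )
    return curves


def write_bundle(bundle: InputBundle, out_dir: str | Path,
                 estate_curve_species: str | None = None) -> Path:
    """Write a bundle as a run directory; returns the run.yaml path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.concat([t.to_frame() for t in bundle.flow_tables.values()]).to_csv(
        out / "flows.csv", index=False
    )
    bundle.inventory.to_csv(out / "inventory.csv")
    bundle.schedule.to_csv(out / "schedule.csv")
    half_lives_to_csv(bundle.half_lives, out / "half_lives.csv")
    curves = dict(bundle.afforestation_curves)
    estate_species = estate_curve_species or bundle.estate_curve.species
    curves.setdefault(bundle.estate_curve.species, bundle.estate_curve)
    _curves_to_frame(curves).to_csv(out / "yield_curves.csv", index=False)

    config = {
        "harvest": bundle.harvest,
        "flows_csv": "flows.csv",
        "inventory_csv": "inventory.csv",
        "schedule_csv": "schedule.csv",
        "half_lives_csv": "half_lives.csv",
        "yield_curves_csv": "yield_curves.csv",
        "woodfuel_import_replacement_fraction":
            bundle.woodfuel_import_replacement_fraction,
        "estate": {
            "area_ha": bundle.estate.area_ha,
            "rotation_baseline": bundle.estate.rotation_baseline,
            "rotation_extended": bundle.estate.rotation_extended,
            "green_t_per_m3": bundle.estate.green_t_per_m3,
            "curve_species": estate_species,
        },
        "convention": {
            "moisture_green": bundle.convention.moisture_green,
            "carbon_dry": bundle.convention.carbon_dry,
        },
        "substitution": {
            "timber_per_wall": bundle.substitution.timber_per_wall,
            "timber_density_20mc": bundle.substitution.timber_density_20mc,
            "concrete_wall_ef": bundle.substitution.concrete_wall_ef,
            "gas_ef": bundle.substitution.gas_ef,
            "wood_energy_yield": bundle.substitution.wood_energy_yield,
            "energy_sector": bundle.substitution.energy_sector,
            "minerals_sector": bundle.substitution.minerals_sector,
        },
        "run": {
            "start_year": 2022,
            "end_year": 2050,
            "implementation_year": 2027,
        },
        "afforestation": {
            "planting_rate_ha": 20000.0,
            "start_year": 2023,
            "end_year": 2050,
            "mix": [
                {"fraction": 0.5, "species": "sitka_spruce"},
                {"fraction": 0.5, "species": "conifer_broadleaf_mix"},
            ]
            if "sitka_spruce" in curves
            else [{"fraction": 1.0, "species": estate_species}],
        },
    }
    path = out / "run.yaml"
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path


def load_bundle(config_path: str | Path) -> tuple[InputBundle, dict]:
    """Load a run directory; returns (bundle, raw config dict)."""
    config_path = Path(config_path)
    base = config_path.parent
    cfg = yaml.safe_load(config_path.read_text())

    flows = pd.read_csv(base / cfg["flows_csv"])
    tables = {
        sid: FlowTable.from_frame(flows, sid)
        for sid in flows["scenario_id"].unique()
    }
    curves = _curves_from_frame(pd.read_csv(base / cfg["yield_curves_csv"]))
    est = cfg.get("estate", {})
    estate_species = est.get("curve_species", next(iter(curves)))
    bundle = InputBundle(
        flow_tables=tables,
        inventory=EmissionFactorInventory.from_csv(base / cfg["inventory_csv"]),
        schedule=DecarbSchedule.from_csv(base / cfg["schedule_csv"]),
        half_lives=half_lives_from_csv(base / cfg["half_lives_csv"]),
        convention=CarbonConvention(**cfg.get("convention", {})),
        substitution=SubstitutionSpec(**cfg.get("substitution", {})),
        estate=EstateConfig(
            **{k: v for k, v in est.items() if k != "curve_species"}
        ),
        estate_curve=curves[estate_species],
        afforestation_curves=curves,
        harvest=float(cfg.get("harvest", 9.5e6)),
        woodfuel_import_replacement_fraction=float(
            cfg.get("woodfuel_import_replacement_fraction", 0.0)
        ),
    )
    return bundle, cfg


def load_run_config(cfg: dict, scenario_id: str,
                    implementation_year: int | None = None) -> ScenarioConfig:
    run = cfg.get("run", {})
    return ScenarioConfig(
        scenario_id=scenario_id,
        start_year=int(run.get("start_year", 2022)),
        end_year=int(run.get("end_year", 2050)),
        implementation_year=int(
            implementation_year
            if implementation_year is not None
            else run.get("implementation_year", 2027)
        ),
    )
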