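"""Scope 1–3 process emissions under stepwise industrial decarbonisation.

Emission factors are pre-characterised GWP100 values (kg CO2e per unit of
activity) attached to a process and a scope; each factor carries a
decarbonisation-sector tag. A decadal step schedule multiplies every factor
by a sector- and year-dependent multiplier in [0, 1], emulating progressive
deployment of zero-emission technology: the multiplier is 1 before the first
step and non-increasing in time.

Value-chain components follow the national accounting breakdown: forestry
operations, sawmilling, wood-panel production (particleboard, MDF and
recycled MDF) and woodfuel production, each priced on the green tonnes the
corresponding process node handles. Changes in imported-HWP volumes relative
to BAU carry processing + transport emissions (the BAU import burden itself
is set to zero by the consequential convention, so BAU yields no import
term).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .wood_flow import HWP_CATEGORIES, FlowTable, ImportDelta

__all__ = [
    "SCOPE13_COMPONENTS",
    "SCOPE4_COMPONENTS",
    "COMPONENTS",
    "COMPONENT_NODES",
    "EmissionFactor",
    "EmissionFactorInventory",
    "DecarbSchedule",
    "decarb_multiplier",
    "component_process_emissions",
    "import_delta_emissions",
]

#: Components carrying Scope 1–3 process emissions, with the flow-network
#: node whose throughput (green tonnes/yr) each is priced on.
COMPONENT_NODES: dict[str, tuple[str, ...]] = {
    "uk_forestry_operations": ("forest_gate",),
    "uk_sawmilling": ("sawmill",),
    "uk_wood_panel_production": ("panel_mill", "mdf_recycling"),
    "uk_woodfuel_production": ("woodfuel_plant",),
}

SCOPE13_COMPONENTS: tuple[str, ...] = tuple(COMPONENT_NODES)

#: Components carrying Scope 4 (avoided) or signed biogenic storage terms.
SCOPE4_COMPONENTS: tuple[str, ...] = (
    "change_in_uk_hwp_c_storage",
    "change_in_import_emissions",
    "avoided_reduced_harvest",
    "avoided_product_substitution",
)

COMPONENTS: tuple[str, ...] = SCOPE13_COMPONENTS + SCOPE4_COMPONENTS


@dataclass(frozen=True)
class EmissionFactor:
    process_id: str
    scope: int  # 1, 2 or 3
    value: float  # kg CO2e per unit
    unit: str  # e.g. "green_tonne", "tkm", "MJ_delivered"
    decarb_sector: str

    def __post_init__(self):
        if self.value < 0:
            raise ValueError(f"emission factor must be >= 0, got {self.value}")
        if self.scope not in (1, 2, 3):
            raise ValueError(f"scope must be 1, 2 or 3, got {self.scope}")


class EmissionFactorInventory:
    """Per-process, per-scope CO2e factors, CSV round-trippable.

    Columns: process_id, scope, value_kgco2e, unit, decarb_sector. Resin
    inputs to panel production are separate rows (process ``panel_mill``,
    scope 3, sector ``chemicals``) so the resin share stays inspectable.
    """

    def __init__(self, factors: Iterable[EmissionFactor]):
        self._factors = list(factors)

    def __iter__(self):
        return iter(self._factors)

    def __len__(self):
        return len(self._factors)

    def for_process(self, process_id: str) -> list[EmissionFactor]:
        return [f for f in self._factors if f.process_id == process_id]

    def require_process(self, process_id: str) -> list[EmissionFactor]:
        out = self.for_process(process_id)
        if not out:
            raise KeyError(f"no emission factors for process {process_id!r}")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "process_id": [f.process_id for f in self._factors],
                "scope": [f.scope for f in self._factors],
                "value_kgco2e": [f.value for f in self._factors],
                "unit": [f.unit for f in self._factors],
                "decarb_sector": [f.decarb_sector for f in self._factors],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EmissionFactorInventory":
        return cls(
            EmissionFactor(
                process_id=str(r.process_id),
                scope=int(r.scope),
                value=float(r.value_kgco2e),
                unit=str(r.unit),
                decarb_sector=str(r.decarb_sector),
            )
            for r in df.itertuples()
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmissionFactorInventory":
        return cls.from_frame(pd.read_csv(path))


class DecarbSchedule:
    """Step-function decarbonisation multipliers per sector.

    ``steps[sector]`` maps a step year to the multiplier that applies from
    that year onward; before the first step the multiplier is 1. Multipliers
    must be in [0, 1] and non-increasing in year.
    """

    def __init__(self, steps: Mapping[str, Mapping[int, float]]):
        self.steps: dict[str, dict[int, float]] = {}
        for sector, seq in steps.items():
            ordered = dict(sorted((int(y), float(m)) for y, m in seq.items()))
            prev = 1.0
            for year, mult in ordered.items():
                if not 0.0 <= mult <= 1.0:
                    raise ValueError(
                        f"multiplier {mult} for {sector!r}@{year} outside [0, 1]"
                    )
                if mult > prev:
                    raise ValueError(
                        f"multipliers for {sector!r} must be non-increasing"
                    )
                prev = mult
            self.steps[sector] = ordered

    def multiplier(self, sector: str, year: int) -> float:
        if sector not in self.steps:
            raise KeyError(f"unknown decarbonisation sector {sector!r}")
        mult = 1.0
        for step_year, m in self.steps[sector].items():
            if year >= step_year:
                mult = m
        return mult

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sector": s, "step_year": y, "multiplier": m}
            for s, seq in self.steps.items()
            for y, m in seq.items()
        ]
        return pd.DataFrame(rows, columns=["sector", "step_year", "multiplier"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DecarbSchedule":
        steps: dict[str, dict[int, float]] = {}
        for r in df.itertuples():
            steps.setdefault(str(r.sector), {})[int(r.step_year)] = float(r.multiplier)
        return cls(steps)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DecarbSchedule":
        return cls.from_frame(pd.read_csv(path))


def decarb_multiplier(sector: str, year: int, schedule: DecarbSchedule) -> float:
    """Multiplier applied to every emission of ``sector`` in ``year``."""
    return schedule.multiplier(sector, year)


def _empty_emissions() -> pd.DataFrame:
    return pd.DataFrame(columns=["component", "scope", "value_tco2e"])


def component_process_emissions(
    table: FlowTable,
    inventory: EmissionFactorInventory,
    year: int,
    schedule: DecarbSchedule,
) -> pd.DataFrame:
    """Scope 1–3 emissions (t CO2e/yr) per value-chain component.

    For each component, value = Σ over its process nodes and factors of
    (node throughput × factor × decarbonisation multiplier). Factors priced
    per green tonne multiply the node's green-tonne throughput; a unit
    mismatch raises.
    """
    rows = []
    for component, nodes in COMPONENT_NODES.items():
        totals: dict[int, float] = {1: 0.0, 2: 0.0, 3: 0.0}
        for node in nodes:
            quantity = table.throughput(node)
            if quantity == 0.0:
                continue
            for f in inventory.require_process(node):
                if f.unit != "green_tonne":
                    raise ValueError(
                        f"factor {f.process_id}/scope{f.scope} has unit "
                        f"{f.unit!r}; flows are green tonnes"
                    )
                mult = schedule.multiplier(f.decarb_sector, year)
                totals[f.scope] += quantity * f.value * mult / 1000.0
        for scope in (1, 2, 3):
            rows.append(
                {"component": component, "scope": scope, "value_tco2e": totals[scope]}
            )
    return pd.DataFrame(rows)


def import_delta_emissions(
    deltas: Sequence[ImportDelta],
    inventory: EmissionFactorInventory,
    year: int,
    schedule: DecarbSchedule,
) -> pd.DataFrame:
    """Emissions from the change in imported-HWP volumes versus BAU.

    Each category's delta volume carries per-unit processing factors equal to
    the domestic ones (``import_processing_<category>`` rows, falling back to
    nothing if a category is never traded) plus an ``import_transport`` factor
    per green tonne. Exporting countries decarbonise on the same schedule.
    All-zero deltas (BAU) give exactly zero. Reported under component
    ``change_in_import_emissions``, scope 4 (signed).
    """
    total = 0.0
    transport_factors = inventory.for_process("import_transport")
    if not transport_factors:
        raise KeyError("no emission factors for process 'import_transport'")
    for d in deltas:
        if d.delta_volume == 0.0:
            continue
        factors = inventory.for_process(f"import_processing_{d.category}")
        for f in factors + transport_factors:
            mult = schedule.multiplier(f.decarb_sector, year)
            total += d.delta_volume * f.value * mult / 1000.0
    return pd.DataFrame(
        [{"component": "change_in_import_emissions", "scope": 4, "value_tco2e": total}]
    )
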