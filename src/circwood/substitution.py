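"""Scope 4 substitution credits: wood energy displacing natural gas, and
construction timber displacing concrete blockwork.

Woodfuel displaces natural-gas energy one-for-one on delivered energy;
construction sawnwood is converted to an area of timber-framed wall
(industry-standard 0.0175 m3 of timber per m2 of wall) which displaces the
same area of single-skin 140-mm concrete block-and-mortar wall. Credits are
negative CO2e and shrink as the displaced sectors decarbonise (the same
decadal step schedule applied to process emissions); they never apply to the
biogenic storage credits. Biogenic CO2 from wood combustion is not added
here -- it is released through the HWP fuelwood pool, avoiding double
counting.
"""

from __future__ import annotations

from dataclasses import dataclass

from .emissions_engine import DecarbSchedule

__all__ = ["SubstitutionSpec", "fuel_substitution_credit",
           "construction_substitution_credit"]


@dataclass(frozen=True)
class SubstitutionSpec:
    """Displacement constants (all positive; all calibration-configurable).

    timber_per_wall: m3 of timber per m2 of wall (industry standard 0.0175);
    timber_density_20mc: kg/m3 at 20% moisture content;
    concrete_wall_ef: kg CO2e per m2 of the displaced 140-mm block wall
    (block + sand + cement at 10:3 sand:cement, 10-mm jointing, composed
    offline from the factor inventory);
    gas_ef: kg CO2e per MJ of delivered natural-gas energy;
    wood_energy_yield: MJ delivered per tonne of wood fuel;
    energy_sector / minerals_sector: decarbonisation-sector tags of the
    displaced gas energy and concrete manufacture.
    """

    timber_per_wall: float = 0.0175
    timber_density_20mc: float = 500.0
    concrete_wall_ef: float = 12.0
    gas_ef: float = 0.07
    wood_energy_yield: float = 9000.0
    energy_sector: str = "energy_supply"
    minerals_sector: str = "minerals"

    def __post_init__(self):
        for name in ("timber_per_wall", "timber_density_20mc",
                     "concrete_wall_ef", "gas_ef", "wood_energy_yield"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def fuel_substitution_credit(
    wood_fuel_t: float,
    spec: SubstitutionSpec,
    year: int,
    schedule: DecarbSchedule,
) -> float:
    """Avoided natural-gas emissions from burning ``wood_fuel_t`` tonnes of
    wood fuel (t CO2e/yr, <= 0).

    credit = -fuel x wood_energy_yield x gas_ef x decarb multiplier of the
    energy-supply sector.
    """
    if wood_fuel_t < 0:
        raise ValueError("wood fuel mass must be non-negative")
    mult = schedule.multiplier(spec.energy_sector, year)
    return -wood_fuel_t * spec.wood_energy_yield * spec.gas_ef * mult / 1000.0


def construction_substitution_credit(
    sawnwood_t_20mc: float,
    spec: SubstitutionSpec,
    year: int,
    schedule: DecarbSchedule,
) -> float:
    """Avoided concrete-wall emissions from ``sawnwood_t_20mc`` tonnes of
    construction timber at 20% moisture (t CO2e/yr, <= 0).

    wall area = (mass / density) / timber_per_wall; credit = -area x
    concrete-wall factor x decarb multiplier of the minerals sector.
    """
    if sawnwood_t_20mc < 0:
        raise ValueError("sawnwood mass must be non-negative")
    volume_m3 = sawnwood_t_20mc * 1000.0 / spec.timber_density_20mc
    wall_m2 = volume_m3 / spec.timber_per_wall
    mult = schedule.multiplier(spec.minerals_sector, year)
    return -wall_m2 * spec.concrete_wall_ef * mult / 1000.0
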