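"""Stand- and estate-level forest carbon: yield curves, rotations,
avoided-harvest credits, afforestation.

The stand model is deliberately transparent: a parametric (Chapman-Richards)
or tabulated age -> standing-volume yield curve, a fixed biomass
expansion x density x carbon product converting stem volume to whole-stand
biomass carbon, and a single first-order soil/dead-organic-matter pool fed by
stand turnover and harvest residues. Clear-fell at rotation age resets the
standing volume to zero and transfers residues to the soil pool.

Two estate-scale results are built from it:

* the avoided-harvest credit: recycling MDF lowers demand for virgin wood,
  modelled as a reference Sitka spruce estate (710,000 ha) moving from a
  50- to a 54-year rotation; the annualised average estate-carbon gain over
  the study period defines a credit per green tonne of avoided harvest,
  scaled by the scenario's recycled-MDF volume;
* the afforestation programme: cohorts planted at a constant annual rate,
  unharvested within the study horizon, superposed to give annual and
  cumulative net sequestration (negative CO2e = removal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hwp_carbon import CO2_PER_C, CarbonConvention

__all__ = [
    "YieldCurve",
    "StandCohort",
    "EstateConfig",
    "AfforestationProgramme",
    "chapman_richards",
    "stand_trajectory",
    "estate_carbon_series",
    "avoided_harvest_credit",
    "weighted_mean_yield_class",
    "afforestation_series",
]


def chapman_richards(age, asymptote: float, rate: float, shape: float):
    """Chapman-Richards cumulative volume curve V(a) = A (1 - e^{-k a})^p."""
    age = np.asarray(age, dtype=float)
    return asymptote * (1.0 - np.exp(-rate * age)) ** shape


@dataclass(frozen=True)
class YieldCurve:
    """Age -> cumulative standing volume (m3/ha), monotone non-decreasing.

    ``yield_class`` is the UK productivity index (maximum mean annual
    increment, m3/ha/yr). Beyond the last tabulated age the curve is held
    flat; volume at age 0 is 0.
    """

    species: str
    yield_class: float
    ages: tuple[float, ...]
    volumes: tuple[float, ...]

    def __post_init__(self):
        if len(self.ages) != len(self.volumes) or not self.ages:
            raise ValueError("ages and volumes must be equal-length, non-empty")
        v = np.asarray(self.volumes)
        if np.any(np.diff(v) < 0) or v[0] < 0:
            raise ValueError("volumes must be non-negative and non-decreasing")

    @classmethod
    def from_chapman_richards(
        cls,
        species: str,
        yield_class: float,
        asymptote: float,
        rate: float,
        shape: float,
        max_age: int = 200,
    ) -> "YieldCurve":
        ages = np.arange(0, max_age + 1, dtype=float)
        vols = chapman_richards(ages, asymptote, rate, shape)
        return cls(species, yield_class, tuple(ages), tuple(vols))

    def volume(self, age) -> np.ndarray:
        """Standing volume (m3/ha) at age, flat extrapolation past the end."""
        return np.interp(np.asarray(age, dtype=float), self.ages, self.volumes)


@dataclass(frozen=True)
class StandCohort:
    """An even-aged stand: area, planting year, rotation and yield curve."""

    area: float  # ha
    plant_year: int
    rotation: int  # years; harvest resets standing volume at this age
    curve: YieldCurve

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError(f"area must be positive, got {self.area}")


#: Whole-stand biomass carbon per m3 of standing stem volume
#: (t C/m3): wood density 0.40 odt/m3 x carbon 0.5 x biomass expansion 1.4.
DEFAULT_BIOMASS_C_PER_M3 = 0.40 * 0.5 * 1.4

#: First-order soil/dead-organic-matter pool parameters (calibration).
DEFAULT_SOIL_DECAY = 0.03  # /yr
DEFAULT_TURNOVER_FRACTION = 0.015  # of standing biomass C entering soil /yr
DEFAULT_RESIDUE_FRACTION = 0.3  # of felled biomass C left on site


def stand_trajectory(
    cohort: StandCohort,
    years: Sequence[int],
    biomass_c_per_m3: float = DEFAULT_BIOMASS_C_PER_M3,
    soil_decay: float = DEFAULT_SOIL_DECAY,
    turnover_fraction: float = DEFAULT_TURNOVER_FRACTION,
    residue_fraction: float = DEFAULT_RESIDUE_FRACTION,
    initial_soil_c: float = 0.0,
) -> pd.DataFrame:
    """Annual biomass and soil carbon (t C) for one cohort.

    Biomass C = area x volume(age) x biomass_c_per_m3, a sawtooth resetting
    to zero at each rotation-age harvest; a fraction of felled biomass plus
    annual turnover feeds a single first-order soil pool. Harvested stem
    carbon leaves the stand (it enters the HWP accounting, not the soil).
    Returns a year-indexed frame with columns biomass_c, soil_c,
    harvested_volume_m3.
    """
    years = list(years)
    soil = initial_soil_c
    prev_biomass = None
    rows = []
    for year in years:
        age = year - cohort.plant_year
        if age < 0:
            rows.append({"year": year, "biomass_c": 0.0, "soil_c": soil,
                         "harvested_volume_m3": 0.0})
            continue
        cycle_age = age % cohort.rotation if cohort.rotation > 0 else age
        harvested_now = age > 0 and cohort.rotation > 0 and cycle_age == 0
        vol = float(cohort.curve.volume(cycle_age))
        biomass = cohort.area * vol * biomass_c_per_m3
        harvest_vol = 0.0
        residue_input = 0.0
        if harvested_now and prev_biomass is not None:
            felled_vol = float(cohort.curve.volume(cohort.rotation))
            harvest_vol = cohort.area * felled_vol
            residue_input = residue_fraction * cohort.area * felled_vol * biomass_c_per_m3
        turnover = turnover_fraction * biomass
        soil = soil * (1.0 - soil_decay) + turnover + residue_input
        rows.append({"year": year, "biomass_c": biomass, "soil_c": soil,
                     "harvested_volume_m3": harvest_vol})
        prev_biomass = biomass
    return pd.DataFrame(rows).set_index("year")


def weighted_mean_yield_class(components: Sequence[tuple[float, float]]) -> float:
    """Aggregate yield class of a species mix: sum of fraction x YC."""
    fracs = [f for f, _ in components]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fracs)}")
    return float(sum(f * yc for f, yc in components))


@dataclass(frozen=True)
class EstateConfig:
    """Reference commercial estate for the avoided-harvest calculation.

    Defaults: the national commercial conifer area (710,000 ha of Sitka
    spruce), fully regulated (equal area in every age class), moving from a
    50- to a 54-year rotation when harvest demand falls.
    """

    area_ha: float = 710_000.0
    rotation_baseline: int = 50
    rotation_extended: int = 54
    green_t_per_m3: float = 1.0  # green tonnes per m3 of harvested stem

    def __post_init__(self):
        if self.rotation_extended < self.rotation_baseline:
            raise ValueError("extended rotation must be >= baseline rotation")


def estate_carbon_series(
    curve: YieldCurve,
    estate: EstateConfig,
    rotation: int,
    n_years: int,
    biomass_c_per_m3: float = DEFAULT_BIOMASS_C_PER_M3,
    soil_decay: float = DEFAULT_SOIL_DECAY,
    turnover_fraction: float = DEFAULT_TURNOVER_FRACTION,
    residue_fraction: float = DEFAULT_RESIDUE_FRACTION,
) -> pd.DataFrame:
    """Total carbon and harvest of a regulated estate switching to
    ``rotation`` at year 0.

    The estate starts in the baseline regulated state (equal area per age
    class 1..rotation_baseline, soil pools at their steady state). Each year
    every cohort ages; cohorts reaching ``rotation`` are clear-felled and
    replanted. Returns a frame indexed 0..n_years-1 with columns total_c
    (biomass + soil, t C) and harvest_green_t.
    """
    base_r = estate.rotation_baseline
    area_per_class = estate.area_ha / base_r
    # regulated initial state: one cohort per age class 0..base_r-1, so each
    # year exactly one class reaches rotation age
    ages = np.arange(0, base_r, dtype=float)
    areas = np.full(base_r, area_per_class)

    def biomass_of(ages_arr, areas_arr):
        return float(np.sum(areas_arr * curve.volume(ages_arr)) * biomass_c_per_m3)

    # steady-state soil pool consistent with the baseline regime:
    # inputs = turnover of regulated biomass + residues of the annual fell
    biomass0 = biomass_of(ages, areas)
    fell_c0 = area_per_class * float(curve.volume(base_r)) * biomass_c_per_m3
    soil = (turnover_fraction * biomass0 + residue_fraction * fell_c0) / soil_decay

    ages = ages.copy()
    rows = []
    for t in range(n_years):
        ages += 1.0
        felled = ages >= rotation
        harvest_vol = float(np.sum(areas[felled] * curve.volume(ages[felled])))
        residue_input = residue_fraction * harvest_vol * biomass_c_per_m3
        ages[felled] = 0.0
        biomass = biomass_of(ages, areas)
        soil = soil * (1.0 - soil_decay) + turnover_fraction * biomass + residue_input
        rows.append(
            {
                "year_index": t,
                "biomass_c": biomass,
                "soil_c": soil,
                "total_c": biomass + soil,
                "harvest_green_t": harvest_vol * estate.green_t_per_m3,
            }
        )
    return pd.DataFrame(rows).set_index("year_index")


def regulated_mean_stock(curve: YieldCurve, rotation: int) -> float:
    """Mean standing volume (m3/ha) of a regulated forest, closed form:
    the age-class average (1/R) * sum_{a=0..R-1} V(a), i.e. the post-harvest
    state with one age class just replanted."""
    ages = np.arange(0, rotation, dtype=float)
    return float(np.mean(curve.volume(ages)))


def avoided_harvest_credit(
    recycled_mdf_green_t: float,
    curve: YieldCurve,
    estate: EstateConfig = EstateConfig(),
    window: int = 28,
    convention: CarbonConvention | None = None,
    **stand_kwargs,
) -> tuple[float, float]:
    """Avoided-harvest credit (t CO2e/yr, <= 0) and the implied estate
    harvest reduction (green tonnes/yr).

    The reference estate's rotation extension defines the carbon gain: the
    annualised average gain over the study window,
    -(mean over window of (extended - baseline estate C)) x (44/12) / window,
    divided by the estate's mean harvest reduction, gives a credit intensity
    per green tonne of avoided harvest; the scenario's recycled-MDF volume
    (in green-tonne equivalents) scales it linearly. Zero recycling => zero
    credit.
    """
    if recycled_mdf_green_t < 0:
        raise ValueError("recycled volume must be non-negative")
    if recycled_mdf_green_t == 0.0:
        return 0.0, 0.0
    base = estate_carbon_series(curve, estate, estate.rotation_baseline,
                                window, **stand_kwargs)
    ext = estate_carbon_series(curve, estate, estate.rotation_extended,
                               window, **stand_kwargs)
    gain = ext["total_c"] - base["total_c"]
    estate_credit = -float(gain.mean()) * CO2_PER_C / window
    harvest_reduction = float(
        (base["harvest_green_t"] - ext["harvest_green_t"]).mean()
    )
    if harvest_reduction <= 0:
        return 0.0, 0.0
    credit = estate_credit * recycled_mdf_green_t / harvest_reduction
    return credit, harvest_reduction


@dataclass(frozen=True)
class AfforestationProgramme:
    """A national planting programme: rate, span and species mix.

    ``mix`` lists (area fraction, label, yield curve) components; fractions
    must sum to 1. Commercial conifer harvest starts 50 years after planting,
    beyond the study horizon, so no harvest occurs within it.
    """

    planting_rate_ha: float
    start_year: int
    end_year: int
    mix: tuple[tuple[float, str, YieldCurve], ...]

    def __post_init__(self):
        if self.start_year > self.end_year:
            raise ValueError("start_year must be <= end_year")
        if not self.mix:
            raise ValueError("mix must not be empty")
        total = sum(f for f, _, _ in self.mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mix fractions must sum to 1, got {total}")


def afforestation_series(
    prog: AfforestationProgramme,
    years: Sequence[int],
    rotation: int = 50,
    **stand_kwargs,
) -> pd.DataFrame:
    """Annual and cumulative net sequestration of the programme (t CO2e).

    One cohort per planting year per mix component, superposed; negative
    values are removals. Returns a year-indexed frame with columns
    annual_tco2e and cumulative_tco2e.
    """
    years = list(years)
    if prog.planting_rate_ha == 0.0:
        zero = pd.DataFrame(
            {"year": years, "annual_tco2e": 0.0, "cumulative_tco2e": 0.0}
        )
        return zero.set_index("year")
    total = pd.Series(0.0, index=pd.Index(years, name="year"))
    for plant_year in range(prog.start_year, prog.end_year + 1):
        for frac, _, curve in prog.mix:
            area = prog.planting_rate_ha * frac
            cohort = StandCohort(
                area=area, plant_year=plant_year, rotation=rotation, curve=curve
            )
            traj = stand_trajectory(cohort, years, **stand_kwargs)
            total = total + traj["biomass_c"] + traj["soil_c"]
    annual_c = total.diff().fillna(total.iloc[0])
    annual = -annual_c * CO2_PER_C
    return pd.DataFrame(
        {"annual_tco2e": annual, "cumulative_tco2e": annual.cumsum()}
    )
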