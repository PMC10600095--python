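"""Harvested-wood-product carbon pools (first-order decay) and storage credits.

Carbon moves from the forest to the HWP pool at harvest and returns to the
atmosphere at product end-of-life. Pools follow the IPCC Tier-1 discrete
annual recurrence with decay constant k = ln2 / half-life:

    stock[t+1] = exp(-k) * stock[t] + (1 - exp(-k)) / k * inflow[t]

which conserves carbon exactly (release = stock + inflow - next_stock >= 0).
Fuelwood is immediate release (half-life 0 by convention). Only domestically
produced HWP are pooled; imported HWP storage is credited to the exporting
country and landfill is out of scope.

The storage credit versus BAU is the annualised average stock gain over a
50-year window, converted to CO2e: a constant annual entry
-(mean stock gain) * (44/12) / window, negative = net removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .wood_flow import HWP_CATEGORIES

__all__ = [
    "CO2_PER_C",
    "CarbonConvention",
    "HwpPool",
    "DEFAULT_HALF_LIVES",
    "pool_step",
    "stock_series",
    "storage_change_credit",
    "half_lives_to_csv",
    "half_lives_from_csv",
]

CO2_PER_C = 44.0 / 12.0


@dataclass(frozen=True)
class CarbonConvention:
    """Mass/carbon conversion constants.

    moisture_green: water fraction of green mass; carbon_dry: carbon fraction
    of dry mass. Defaults (0.5 / 0.5) are standard softwood assumptions.
    """

    moisture_green: float = 0.5
    carbon_dry: float = 0.5
    co2_per_c: float = CO2_PER_C
    #: product density (kg/m3) at the stated moisture, per category
    densities: Mapping[str, float] = field(
        default_factory=lambda: {"recycled_mdf": 700.0}
    )

    def __post_init__(self):
        for name in ("moisture_green", "carbon_dry"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def green_tonnes_to_c(self, green_tonnes: float) -> float:
        """Green tonnes -> tonnes of carbon."""
        return green_tonnes * (1.0 - self.moisture_green) * self.carbon_dry


#: Default product half-lives (years); 0 means immediate release (fuelwood).
#: The longer sawnwood and shorter panel lives follow common national HWP
#: reporting assumptions; values are calibration, configurable per run.
DEFAULT_HALF_LIVES: dict[str, float] = {
    "carcassing": 35.0,
    "fencing": 15.0,
    "fence_poles": 15.0,
    "packaging_pallets": 2.0,
    "particleboard": 25.0,
    "mdf": 25.0,
    "recycled_mdf": 25.0,
    "woodfuel": 0.0,
    "other": 15.0,
}


@dataclass
class HwpPool:
    """One product category's carbon pool."""

    category: str
    half_life: float  # years; 0 => immediate release
    stock: float = 0.0  # t C

    def step(self, inflow: float) -> float:
        """Advance one year; returns the carbon released (t C/yr)."""
        next_stock, release = pool_step(self.stock, inflow, self.half_life)
        self.stock = next_stock
        return release


def pool_step(
    stock: float, inflow: float, half_life: float
) -> tuple[float, float]:
    """One annual step of the first-order decay recurrence.

    Returns (next_stock, release); release = stock + inflow - next_stock,
    so carbon is conserved to machine precision. half_life <= 0 means the
    whole pool plus inflow is released within the year.
    """
    if stock < 0 or inflow < 0:
        raise ValueError("stock and inflow must be non-negative")
    if half_life <= 0:
        return 0.0, stock + inflow
    k = math.log(2.0) / half_life
    decay = math.exp(-k)
    # -expm1(-k)/k stays accurate as k -> 0 (very long-lived products)
    next_stock = decay * stock + (-math.expm1(-k)) / k * inflow
    return next_stock, stock + inflow - next_stock


def stock_series(
    production: pd.DataFrame, half_lives: Mapping[str, float]
) -> pd.DataFrame:
    """Evolve all category pools over a production series.

    ``production`` is a year-indexed DataFrame with one column per category
    (t C/yr inflows, domestically produced HWP only). Returns a tidy frame
    with columns year, category, stock_tC, release_tC. Cumulative release
    plus final stock equals cumulative inflow for every category.
    """
    missing = [c for c in production.columns if c not in half_lives]
    if missing:
        raise KeyError(f"no half-life for categories: {missing}")
    rows = []
    for cat in production.columns:
        pool = HwpPool(category=cat, half_life=float(half_lives[cat]))
        for year, inflow in production[cat].items():
            release = pool.step(float(inflow))
            rows.append(
                {
                    "year": int(year),
                    "category": cat,
                    "stock_tC": pool.stock,
                    "release_tC": release,
                }
            )
    return pd.DataFrame(rows, columns=["year", "category", "stock_tC", "release_tC"])


def total_stock(series: pd.DataFrame) -> pd.Series:
    """Total stock (t C) per year across categories."""
    return series.groupby("year")["stock_tC"].sum()


def storage_change_credit(
    scenario_series: pd.DataFrame,
    bau_series: pd.DataFrame,
    window: int = 50,
) -> float:
    """Annualised HWP storage credit versus BAU (t CO2e/yr, <= 0 if storing).

    credit = -(mean over the first ``window`` years of the total stock gain,
    scenario minus BAU) * (44/12) / window, reported as a constant annual
    entry. Identical series give exactly zero (the BAU convention).
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    s = total_stock(scenario_series)
    b = total_stock(bau_series)
    diff = (s - b).dropna()
    gain = diff.iloc[:window]
    if gain.empty:
        return 0.0
    return -float(gain.mean()) * CO2_PER_C / window


def half_lives_to_csv(half_lives: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"category": list(half_lives), "half_life_years": list(half_lives.values())}
    ).to_csv(path, index=False)


def half_lives_from_csv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path)
    return {str(r.category): float(r.half_life_years) for r in df.itertuples()}
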