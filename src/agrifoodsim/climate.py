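"""Scenario-dependent climate yield-shock paths and baseline productivity.

NoCC is a constant-2005-climate counterfactual (all shock multipliers are
exactly 1).  CC is a severe climate scenario whose 2030 endpoints are fixed
by region (production-value-weighted -7% Africa, -5% developing, -6% world)
with per-commodity dispersion drawn once per world seed; shocks phase in
linearly from 1.0 in 2010 to the endpoint in 2030 and keep the endpoint
slope thereafter, clipped at the admissible floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .world import BASE_YEAR, WorldConfig

SCENARIO_CLIMATES = ("NoCC", "CC")


class ClimateError(ValueError):
    pass


@dataclass
class ClimateShockPath:
    """Multiplicative yield-shock paths s_{r,c,t} for one climate scenario."""

    scenario: str
    years: np.ndarray
    shocks: dict[int, pd.DataFrame]  # year -> leaf region x commodity multipliers

    def at(self, year: int) -> pd.DataFrame:
        return self.shocks[int(year)]


def _phase_in(endpoint: float, year: int) -> float:
    frac = (year - BASE_YEAR) / (2030 - BASE_YEAR)
    return 1.0 + (endpoint - 1.0) * frac


def shock_path(world: WorldConfig, scenario: str) -> ClimateShockPath:
    if scenario not in SCENARIO_CLIMATES:
        raise ClimateError(f"unknown climate scenario {scenario!r}; "
                           f"expected one of {SCENARIO_CLIMATES}")
    years = world.years
    shocks = {}
    ones = pd.DataFrame(1.0, index=world.leaf_regions, columns=world.commodity_ids)
    for y in years:
        if scenario == "NoCC" or y <= BASE_YEAR:
            shocks[int(y)] = ones.copy()
        else:
            frac = (y - BASE_YEAR) / (2030 - BASE_YEAR)
            shocks[int(y)] = (1.0 + (world.cc_shock_2030 - 1.0) * frac).clip(lower=0.501)
    return ClimateShockPath(scenario, years, shocks)


def shock_at(world: WorldConfig, scenario: str, region: str, commodity: str,
             year: int) -> float:
    """Yield-shock multiplier for one region/commodity/year.

    Aggregate regions return the production-value-weighted mean of their
    leaves, so (CC, Africa, 2030) returns the configured -7% endpoint.
    """
    if scenario not in SCENARIO_CLIMATES:
        raise ClimateError(f"unknown climate scenario {scenario!r}")
    if not (BASE_YEAR <= year <= world.horizon):
        raise ClimateError(f"year {year} outside [{BASE_YEAR}, {world.horizon}]")
    if scenario == "NoCC":
        return 1.0
    table = shock_path(world, scenario).at(year)
    leaves = world.leaves_under(region)
    if commodity == "all":
        w = world.production_value_weights(region)
        return float((w * table.loc[leaves]).to_numpy().sum())
    value = world.production.loc[leaves, commodity] * world.prices[commodity]
    w = value / value.sum()
    return float((w * table.loc[leaves, commodity]).sum())


def baseline_productivity_path(world: WorldConfig, region: str, commodity: str = "all"
                               ) -> pd.Series:
    """Cumulative intrinsic-productivity multipliers (NoCC), base year = 1.

    With default calibration the Africa production-weighted 2030 value is
    1.38 and the developing-world value 1.32.
    """
    years = world.years
    leaves = world.leaves_under(region)
    t = years - world.base_year
    if commodity == "all":
        w = world.production_value_weights(region)
        path = np.zeros(len(years))
        for i, ti in enumerate(t):
            mult = (1.0 + world.intrinsic_yield_growth.loc[leaves]) ** ti
            path[i] = float((w * mult).to_numpy().sum())
    else:
        value = world.production.loc[leaves, commodity] * world.prices[commodity]
        w = value / value.sum()
        g = world.intrinsic_yield_growth.loc[leaves, commodity]
        path = np.array([float((w * (1.0 + g) ** ti).sum()) for ti in t])
    return pd.Series(path, index=years)


def shocks_to_frame(path: ClimateShockPath) -> pd.DataFrame:
    """Long-format export: region, commodity, year, multiplier."""
    rows = []
    for y in path.years:
        tab = path.at(int(y))
        for r in tab.index:
            for c in tab.columns:
                rows.append((r, c, int(y), float(tab.at[r, c])))
    return pd.DataFrame(rows, columns=["region", "commodity", "year", "multiplier"])
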