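"""SSP2-style population and GDP trajectories.

Levels are compounded geometrically; between printed decade anchors
(2010/2020/2030) the path is geometric interpolation, which reproduces the
anchor levels exactly and implies a constant within-decade growth rate.
Aggregates are sums of their children; average income is always recomputed
from summed GDP and population, never averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .world import WorldConfig


class MacroError(ValueError):
    pass


@dataclass
class MacroTrajectory:
    """Population (millions) and GDP (trillion 2005 USD) paths for a region."""

    region_id: str
    years: np.ndarray
    population: np.ndarray
    gdp: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.population <= 0) or np.any(self.gdp <= 0):
            raise MacroError(f"non-positive population or GDP for {self.region_id}")

    def index_of(self, year: int) -> int:
        if not (self.years[0] <= year <= self.years[-1]):
            raise MacroError(f"year {year} outside trajectory of {self.region_id}")
        return int(year - self.years[0])


def project_series(base_value: float, cagr: float, years: int) -> np.ndarray:
    """Exact compounding: value_t = base * (1 + cagr)^t for t = 0..years.

    ``cagr`` is a fraction per year (0.052 for 5.2 %/yr).
    """
    if base_value <= 0:
        raise MacroError("base_value must be positive")
    if years < 0:
        raise MacroError("years must be non-negative")
    if cagr <= -1.0:
        raise MacroError("growth rate at or below -100 %/yr is undefined")
    return base_value * (1.0 + cagr) ** np.arange(years + 1)


def geometric_interpolate(years: np.ndarray, anchor_years: list[int],
                          anchor_values: list[float]) -> np.ndarray:
    """Piecewise-geometric path through decade anchors (log-linear in time)."""
    anchor_years = np.asarray(anchor_years, dtype=float)
    anchor_values = np.asarray(anchor_values, dtype=float)
    if np.any(anchor_values <= 0):
        raise MacroError("anchors must be positive for geometric interpolation")
    return np.exp(np.interp(years.astype(float), anchor_years, np.log(anchor_values)))


def average_income(traj: MacroTrajectory, year: int) -> float:
    """Average annual income, thousand USD per person.

    GDP in trillion over population in millions is million-USD per person
    times 1e-3 -> multiply by 1000 to land on thousand USD/person.
    """
    i = traj.index_of(year)
    if traj.population[i] == 0:
        raise MacroError("population is zero")
    return float(traj.gdp[i] / traj.population[i] * 1000.0)


def aggregate_regions(trajs: dict[str, MacroTrajectory], aggregate: str,
                      child_ids: list[str]) -> MacroTrajectory:
    """Sum population and GDP across the named children of ``aggregate``."""
    missing = [c for c in child_ids if c not in trajs]
    if missing:
        raise MacroError(f"missing child trajectories for {aggregate}: {missing}")
    first = trajs[child_ids[0]]
    pop = np.zeros_like(first.population, dtype=float)
    gdp = np.zeros_like(first.gdp, dtype=float)
    for c in child_ids:
        t = trajs[c]
        if not np.array_equal(t.years, first.years):
            raise MacroError(f"year grids differ between {child_ids[0]} and {c}")
        pop += t.population
        gdp += t.gdp
    return MacroTrajectory(aggregate, first.years.copy(), pop, gdp)


def trajectories_from_world(world: WorldConfig) -> dict[str, MacroTrajectory]:
    """Leaf trajectories interpolated through the world's SSP2 decade anchors.

    Horizons beyond 2030 extrapolate at the 2020-2030 within-decade rate.
    """
    years = world.years
    out: dict[str, MacroTrajectory] = {}
    for r in world.leaf_regions:
        row = world.macro_anchors.loc[r]
        anchors_y = [2010, 2020, 2030]
        pop_a = [row["pop_2010"], row["pop_2020"], row["pop_2030"]]
        gdp_a = [row["gdp_2010"], row["gdp_2020"], row["gdp_2030"]]
        if world.horizon > 2030:
            g_pop = (pop_a[2] / pop_a[1]) ** 0.1
            g_gdp = (gdp_a[2] / gdp_a[1]) ** 0.1
            anchors_y = anchors_y + [world.horizon]
            pop_a = pop_a + [pop_a[2] * g_pop ** (world.horizon - 2030)]
            gdp_a = gdp_a + [gdp_a[2] * g_gdp ** (world.horizon - 2030)]
        out[r] = MacroTrajectory(
            r, years,
            geometric_interpolate(years, anchors_y, pop_a),
            geometric_interpolate(years, anchors_y, gdp_a),
        )
    return out


def region_trajectory(world: WorldConfig, region_id: str,
                      leaf_trajs: dict[str, MacroTrajectory]) -> MacroTrajectory:
    leaves = world.leaves_under(region_id)
    if len(leaves) == 1 and leaves[0] == region_id:
        return leaf_trajs[region_id]
    return aggregate_regions(leaf_trajs, region_id, leaves)
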