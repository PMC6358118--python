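"""Unit-cost capital costing and baseline investment streams.

Irrigation expansion, water-use-efficiency, soil-management, and
infrastructure investments are costed with regional unit costs: the
annualized stream is construction capex spread over the installation years
plus a maintenance fraction applied to the cumulatively installed cost.
Unit costs are derived by inverting that formula against the printed COMP
cost totals and physical targets, so the fixture table carries realistic
magnitudes (about 10,500 USD per incremental irrigated hectare in Africa
South of the Sahara).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pim import InvestmentStream

COST_REGIONS = ("SSA", "NAWA", "ODV")
CAPITAL_CATEGORIES = ("irrigation_expansion", "water_use_efficiency",
                      "soil_management", "infrastructure")

# Physical increments implied by the scenario targets (applied to assumed
# 2030 baseline stocks): irrigation in million incremental hectares; water
# use efficiency in percentage points; soil and infrastructure in composite
# index points.
BASELINE_IRRIGATED_AREA_2030 = {"SSA": 12.0, "NAWA": 26.0, "ODV": 200.0}  # Mha
INFRA_COMPOSITE_UNITS = {"SSA": 100.0, "NAWA": 100.0, "ODV": 100.0}

DEFAULT_MAINTENANCE = 0.02
INTERVENTION_START = 2015
INTERVENTION_END = 2030


class CostingError(ValueError):
    pass


@dataclass
class UnitCostTable:
    """Regional unit costs (billion USD per physical unit) and maintenance."""

    costs: pd.DataFrame  # region x category
    maintenance: float = DEFAULT_MAINTENANCE

    def __post_init__(self) -> None:
        if (self.costs.to_numpy() <= 0).any():
            raise CostingError("all unit costs must be positive")
        if not (0.0 <= self.maintenance < 1.0):
            raise CostingError("maintenance fraction must lie in [0, 1)")

    def cost(self, region: str, category: str) -> float:
        try:
            return float(self.costs.at[region, category])
        except KeyError as exc:
            raise CostingError(
                f"missing unit cost for {region}/{category}") from exc


@dataclass
class CapitalTargets:
    """Physical increments by region x category (zero means no intervention)."""

    increments: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.increments.to_numpy() < 0).any():
            raise CostingError("capital targets must be non-negative")


def annualization_factor(years: int, maintenance: float) -> float:
    """Average annual cost per unit of total installed cost, for linear
    installation over ``years`` years: capex spread plus maintenance on the
    average cumulative installed fraction (years+1)/(2*years)."""
    avg_cum_frac = (years + 1) / (2.0 * years)
    return 1.0 / years + maintenance * avg_cum_frac


def cost_capital(targets: CapitalTargets, unit_costs: UnitCostTable,
                 years: np.ndarray, start: int = INTERVENTION_START,
                 end: int = INTERVENTION_END) -> list[InvestmentStream]:
    """Annualized capital investment streams per region x category.

    Installation is linear over (start, end]; each year carries its share of
    capex plus maintenance on everything installed so far.  Costs are linear
    in both increments and unit costs.
    """
    n_years = end - start
    streams = []
    for region in targets.increments.index:
        for category in targets.increments.columns:
            inc = float(targets.increments.at[region, category])
            amounts = np.zeros(len(years))
            if inc > 0:
                uc = unit_costs.cost(region, category)
                total_capex = inc * uc
                for i, y in enumerate(years):
                    if start < y <= end:
                        k = y - start
                        amounts[i] = (total_capex / n_years
                                      + unit_costs.maintenance * total_capex * k / n_years)
            streams.append(InvestmentStream(region, "capital", category,
                                            np.asarray(years), amounts))
    return streams


def average_annual_cost(streams: list[InvestmentStream], region: str,
                        category: str, start: int = INTERVENTION_START,
                        end: int = INTERVENTION_END) -> float:
    for s in streams:
        if s.region_id == region and s.category == category:
            return s.average(start + 1, end)
    raise CostingError(f"no stream for {region}/{category}")


def derive_unit_costs(comp_cost_table: pd.DataFrame,
                      comp_targets: pd.DataFrame,
                      maintenance: float = DEFAULT_MAINTENANCE) -> UnitCostTable:
    """Back out unit costs from printed average annual COMP costs and the
    physical increments implied by the scenario target table.

    ``comp_cost_table``: region x category average annual cost (billion/yr).
    ``comp_targets``: region x category percent targets.
    """
    n_years = INTERVENTION_END - INTERVENTION_START
    factor = annualization_factor(n_years, maintenance)
    rows = {}
    for region in COST_REGIONS:
        incs = physical_increments(region, comp_targets)
        rows[region] = {
            cat: float(comp_cost_table.at[region, cat]) / (incs[cat] * factor)
            for cat in CAPITAL_CATEGORIES
        }
    costs = pd.DataFrame(rows).T[list(CAPITAL_CATEGORIES)]
    return UnitCostTable(costs, maintenance)


def physical_increments(region: str, comp_targets: pd.DataFrame) -> dict[str, float]:
    """Convert percent targets into physical units for one costing region."""
    irr_pct = float(comp_targets.at[region, "irrigation_expansion"])
    wue_pts = float(comp_targets.at[region, "water_use_efficiency"])
    soil_pts = float(comp_targets.at[region, "soil_management"])
    return {
        "irrigation_expansion": irr_pct / 100.0 * BASELINE_IRRIGATED_AREA_2030[region],
        "water_use_efficiency": wue_pts,
        "soil_management": soil_pts,
        "infrastructure": INFRA_COMPOSITE_UNITS[region],
    }


# ---------------------------------------------------------------------------
# Baseline R&D streams.  Regional averages over 2010-2030 follow the printed
# baseline cost table (CGIAR: SSA 0.68, NAWA 0.06, ODV 0.41 billion/yr;
# NARS: 0.85 / 1.12 / 3.38), with CGIAR growing 6.3 %/yr to 2030 and NARS
# about 2 %/yr (a >50 % rise by 2030).
BASELINE_CGIAR_AVG = {"SSA": 0.68, "NAWA": 0.06, "ODV": 0.41}
BASELINE_NARS_AVG = {"SSA": 0.85, "NAWA": 1.12, "ODV": 3.38}
CGIAR_GROWTH_TO_2030 = 0.063
CGIAR_GROWTH_TO_2050 = 0.041
NARS_GROWTH = 0.02


def baseline_rnd_stream(region: str, institution: str,
                        years: np.ndarray) -> InvestmentStream:
    """Baseline R&D investment stream whose 2010-2030 average matches the
    printed baseline table."""
    years = np.asarray(years, dtype=int)
    if institution == "CGIAR":
        avg, g = BASELINE_CGIAR_AVG[region], CGIAR_GROWTH_TO_2030
    elif institution == "NARS":
        avg, g = BASELINE_NARS_AVG[region], NARS_GROWTH
    else:
        raise CostingError(f"no baseline R&D stream for {institution}")
    t = years - years[0]
    growth = (1.0 + g) ** t
    mask = years <= 2030
    if institution == "CGIAR" and years[-1] > 2030:
        growth[~mask] = growth[mask][-1] * (1.0 + CGIAR_GROWTH_TO_2050) ** (
            years[~mask] - 2030)
    level0 = avg * mask.sum() / growth[mask].sum()
    return InvestmentStream(region, institution, "R&D", years, level0 * growth)
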