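"""Synthetic world construction and validation.

``build_world`` generates a seeded synthetic agri-food world with the
statistical structure the foresight analysis assumes: a 2010 base year that
clears every commodity market globally, per-capita dietary energy levels
that reproduce the 2010 anchors (Africa ~2500, developing ~2700,
Eastern/Central Africa ~2100 kcal/person/day), constant-elasticity
supply/demand behaviour, intrinsic productivity growth calibrated to the
no-climate-change aggregates (+38% Africa, +32% developing by 2030), and
climate-shock endpoints (-7% Africa, -5% developing, -6% world by 2030).

Base-year calibration order: regional food demand levels are drawn from the
kcal anchors and diet-composition shares; world supply is then set equal to
world demand per commodity and allocated to regions by production shares,
which guarantees the base year is itself a market equilibrium at the base
prices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import geography as geo
from .geography import (
    AFR, CAF, DEV, DVG, EAF, NAF, ODV, SAF, SSA, WAF, WLD,
    COMMODITY_GROUPS, KCAL_PER_KG, LEAF_REGIONS, REGION_NAMES,
    Commodity, Geography,
)

BASE_YEAR = 2010
DEFAULT_HORIZON = 2030

# ---------------------------------------------------------------------------
# Study conditions: fixed 2010 anchors and stylized structural tables.
# Population (millions) and GDP (trillion 2005 USD) at the 2010/2020/2030
# SSP2 anchors, per leaf region.
MACRO_ANCHORS = {
    #        pop2010 pop2020 pop2030  gdp2010 gdp2020 gdp2030
    NAF: (223.0, 260.0, 293.0, 1.2, 1.8, 2.9),
    WAF: (304.0, 386.0, 479.0, 0.5, 1.0, 1.9),
    EAF: (321.0, 407.0, 498.0, 0.3, 0.6, 1.1),
    CAF: (127.0, 162.0, 200.0, 0.2, 0.4, 0.6),
    SAF: (58.0, 63.0, 68.0, 0.5, 0.8, 1.1),
    ODV: (4508.0, 4903.0, 5205.0, 26.6, 48.4, 76.1),
    DEV: (1102.0, 1167.0, 1222.0, 36.1, 45.3, 55.0),
}

# 2010 dietary energy availability anchors, kcal/person/day.  Western Africa
# and other-developing are solved so the Africa aggregate hits 2500 and the
# developing aggregate hits 2700 exactly (population-weighted).
KCAL_ANCHORS_FIXED = {NAF: 3000.0, EAF: 2150.0, CAF: 2050.0, SAF: 2950.0, DEV: 3400.0}
KCAL_TARGET_AFRICA = 2500.0
KCAL_TARGET_DEVELOPING = 2700.0

# Diet composition: share of dietary energy by commodity group.
DIET_SHARES = pd.DataFrame(
    {
        "cereals":      {NAF: 0.52, WAF: 0.42, EAF: 0.48, CAF: 0.35, SAF: 0.52, ODV: 0.50, DEV: 0.30},
        "meats":        {NAF: 0.08, WAF: 0.06, EAF: 0.06, CAF: 0.05, SAF: 0.11, ODV: 0.11, DEV: 0.22},
        "pulses":       {NAF: 0.04, WAF: 0.06, EAF: 0.08, CAF: 0.05, SAF: 0.03, ODV: 0.04, DEV: 0.02},
        "roots_tubers": {NAF: 0.03, WAF: 0.20, EAF: 0.12, CAF: 0.30, SAF: 0.04, ODV: 0.04, DEV: 0.04},
        "oils":         {NAF: 0.12, WAF: 0.12, EAF: 0.08, CAF: 0.12, SAF: 0.11, ODV: 0.11, DEV: 0.15},
        "sugar":        {NAF: 0.09, WAF: 0.04, EAF: 0.06, CAF: 0.04, SAF: 0.10, ODV: 0.08, DEV: 0.12},
        "fruits_veg":   {NAF: 0.12, WAF: 0.10, EAF: 0.12, CAF: 0.09, SAF: 0.09, ODV: 0.12, DEV: 0.15},
    }
).loc[list(LEAF_REGIONS)]

# Regional shares of world production per commodity group (columns sum to 1).
PRODUCTION_SHARES = pd.DataFrame(
    {
        "cereals":      {NAF: 0.02, WAF: 0.03, EAF: 0.03, CAF: 0.01, SAF: 0.01, ODV: 0.55, DEV: 0.35},
        "meats":        {NAF: 0.01, WAF: 0.01, EAF: 0.02, CAF: 0.01, SAF: 0.01, ODV: 0.49, DEV: 0.45},
        "pulses":       {NAF: 0.01, WAF: 0.05, EAF: 0.06, CAF: 0.01, SAF: 0.01, ODV: 0.66, DEV: 0.20},
        "roots_tubers": {NAF: 0.01, WAF: 0.12, EAF: 0.06, CAF: 0.06, SAF: 0.01, ODV: 0.57, DEV: 0.17},
        "oils":         {NAF: 0.01, WAF: 0.04, EAF: 0.02, CAF: 0.01, SAF: 0.01, ODV: 0.61, DEV: 0.30},
        "sugar":        {NAF: 0.02, WAF: 0.01, EAF: 0.02, CAF: 0.01, SAF: 0.02, ODV: 0.62, DEV: 0.30},
        "fruits_veg":   {NAF: 0.03, WAF: 0.03, EAF: 0.03, CAF: 0.01, SAF: 0.01, ODV: 0.64, DEV: 0.25},
    }
).loc[list(LEAF_REGIONS)]

# 2010 world reference prices, constant 2005 USD per tonne.
BASE_PRICES = {
    "cereals": 220.0,
    "meats": 2500.0,
    "pulses": 500.0,
    "roots_tubers": 250.0,
    "oils": 900.0,
    "sugar": 350.0,
    "fruits_veg": 450.0,
}

# Marketing margin (total farm-gate-to-consumer wedge as a fraction of the
# world reference price), by region.
MARGINS = {NAF: 0.25, WAF: 0.40, EAF: 0.42, CAF: 0.45, SAF: 0.22, ODV: 0.25, DEV: 0.10}

# Food value-added share of GDP, used by the income feedback.
FOOD_VA_SHARES = {NAF: 0.14, WAF: 0.32, EAF: 0.35, CAF: 0.30, SAF: 0.10, ODV: 0.12, DEV: 0.03}

# Demand income elasticities by commodity group and development class
# (stylized Engel-consistent values; the source model's are unpublished).
INCOME_ELASTICITIES = pd.DataFrame(
    {
        "africa": {"cereals": 0.20, "meats": 0.42, "pulses": 0.25, "roots_tubers": 0.22,
                   "oils": 0.30, "sugar": 0.28, "fruits_veg": 0.35},
        "odv":    {"cereals": 0.30, "meats": 0.48, "pulses": 0.30, "roots_tubers": 0.25,
                   "oils": 0.38, "sugar": 0.35, "fruits_veg": 0.42},
        "dev":    {"cereals": 0.08, "meats": 0.15, "pulses": 0.10, "roots_tubers": 0.05,
                   "oils": 0.12, "sugar": 0.10, "fruits_veg": 0.15},
    }
)

# Supply responds through combined area and yield adjustment; livestock
# supply is substantially more price-elastic than crop supply.
SUPPLY_PRICE_ELASTICITIES = {
    "cereals": 0.40, "meats": 0.65, "pulses": 0.40, "roots_tubers": 0.40,
    "oils": 0.40, "sugar": 0.40, "fruits_veg": 0.40,
}
DEMAND_PRICE_ELASTICITY = -0.35

# 2010->2030 cumulative productivity multipliers under constant climate
# (production-value-weighted targets; Africa +38%, developing +32%).
PRODUCTIVITY_MULT_AFRICA = 1.38
PRODUCTIVITY_MULT_DEVELOPING = 1.32
PRODUCTIVITY_MULT_DEVELOPED = 1.25

# 2030 climate yield-shock endpoints (multipliers on yields).
CC_SHOCK_AFRICA = 0.93
CC_SHOCK_DEVELOPING = 0.95
CC_SHOCK_WORLD = 0.94
CC_COMMODITY_DISPERSION = 0.03  # +/- around the regional mean, recentred


class WorldConfigError(ValueError):
    """Raised when a synthetic world cannot satisfy its configuration."""


@dataclass
class ElasticityBlock:
    """Constant-elasticity behavioural parameters, region x commodity."""

    supply_price: pd.DataFrame
    demand_price: pd.DataFrame
    demand_income: pd.DataFrame
    demand_cross: Optional[dict[str, pd.DataFrame]] = None


@dataclass
class WorldConfig:
    """The whole synthetic world: geography, commodities, baselines, behaviour."""

    regions: dict[str, Geography]
    commodities: dict[str, Commodity]
    base_year: int
    horizon: int
    production: pd.DataFrame      # Mt, leaf region x commodity, 2010
    consumption: pd.DataFrame     # Mt, leaf region x commodity, 2010
    prices: pd.Series             # USD/t world reference price per commodity
    margins: pd.DataFrame         # wedge fraction, leaf region x commodity
    elasticities: ElasticityBlock
    intrinsic_yield_growth: pd.DataFrame  # fraction/yr, leaf region x commodity
    cc_shock_2030: pd.DataFrame   # 2030 shock multiplier, leaf x commodity
    macro_anchors: pd.DataFrame   # leaf region rows: pop/gdp at 2010/2020/2030
    seed: int

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.base_year, self.horizon + 1)

    @property
    def leaf_regions(self) -> list[str]:
        return list(self.production.index)

    @property
    def commodity_ids(self) -> list[str]:
        return list(self.production.columns)

    def leaves_under(self, region_id: str) -> list[str]:
        return geo.leaves_under(region_id, self.regions)

    def production_value_weights(self, region_id: str) -> pd.DataFrame:
        """Base-year production value by leaf x commodity under ``region_id``."""
        leaves = self.leaves_under(region_id)
        value = self.production.loc[leaves] * self.prices
        return value / value.to_numpy().sum()

    def kcal_per_capita(self, region_id: str, consumption: Optional[pd.DataFrame] = None,
                        population: Optional[float] = None) -> float:
        """2010 kcal/person/day implied by (default: base-year) consumption."""
        cons = self.consumption if consumption is None else consumption
        leaves = self.leaves_under(region_id)
        kcal_per_kg = pd.Series({c: self.commodities[c].kcal_per_kg for c in cons.columns})
        total_kcal = float((cons.loc[leaves] * kcal_per_kg).to_numpy().sum()) * 1e9
        if population is None:
            population = float(self.macro_anchors.loc[leaves, "pop_2010"].sum())
        return total_kcal / (population * 1e6 * 365.0)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        def df(d: pd.DataFrame) -> dict:
            return {"index": list(d.index), "columns": list(d.columns),
                    "data": d.to_numpy().tolist()}

        payload = {
            "seed": self.seed,
            "base_year": self.base_year,
            "horizon": self.horizon,
            "regions": {r: {"name": g.name, "parent": g.parent,
                            "food_va_share": g.food_va_share}
                        for r, g in sorted(self.regions.items())},
            "commodities": {c: {"group": k.group, "kcal_per_kg": k.kcal_per_kg}
                            for c, k in sorted(self.commodities.items())},
            "production": df(self.production),
            "consumption": df(self.consumption),
            "prices": self.prices.to_dict(),
            "margins": df(self.margins),
            "supply_price": df(self.elasticities.supply_price),
            "demand_price": df(self.elasticities.demand_price),
            "demand_income": df(self.elasticities.demand_income),
            "intrinsic_yield_growth": df(self.intrinsic_yield_growth),
            "cc_shock_2030": df(self.cc_shock_2030),
            "macro_anchors": df(self.macro_anchors),
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "WorldConfig":
        raw = json.loads(text)

        def df(d: dict) -> pd.DataFrame:
            return pd.DataFrame(d["data"], index=d["index"], columns=d["columns"])

        regions = {r: Geography(r, v["name"], v["parent"], v["food_va_share"])
                   for r, v in raw["regions"].items()}
        commodities = {c: Commodity(c, v["group"], v["kcal_per_kg"])
                       for c, v in raw["commodities"].items()}
        return cls(
            regions=regions,
            commodities=commodities,
            base_year=raw["base_year"],
            horizon=raw["horizon"],
            production=df(raw["production"]),
            consumption=df(raw["consumption"]),
            prices=pd.Series(raw["prices"]).loc[df(raw["production"]).columns],
            margins=df(raw["margins"]),
            elasticities=ElasticityBlock(
                supply_price=df(raw["supply_price"]),
                demand_price=df(raw["demand_price"]),
                demand_income=df(raw["demand_income"]),
            ),
            intrinsic_yield_growth=df(raw["intrinsic_yield_growth"]),
            cc_shock_2030=df(raw["cc_shock_2030"]),
            macro_anchors=df(raw["macro_anchors"]),
            seed=raw["seed"],
        )


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------

def _jitter(rng: np.random.Generator, frame: pd.DataFrame, rel: float) -> pd.DataFrame:
    noise = rng.normal(0.0, rel, size=frame.shape)
    return frame * np.exp(noise)


def _solve_kcal_anchors() -> dict[str, float]:
    """Solve Western-Africa and other-developing kcal so the aggregates hit
    the Africa=2500 and developing=2700 anchors exactly."""
    pop = {r: MACRO_ANCHORS[r][0] for r in LEAF_REGIONS}
    anchors = dict(KCAL_ANCHORS_FIXED)
    africa = [NAF, WAF, EAF, CAF, SAF]
    known = sum(pop[r] * anchors[r] for r in africa if r != WAF)
    pop_africa = sum(pop[r] for r in africa)
    anchors[WAF] = (KCAL_TARGET_AFRICA * pop_africa - known) / pop[WAF]
    pop_dvg = pop_africa + pop[ODV]
    anchors[ODV] = (KCAL_TARGET_DEVELOPING * pop_dvg
                    - KCAL_TARGET_AFRICA * pop_africa) / pop[ODV]
    for r, v in anchors.items():
        if v <= 0:
            raise WorldConfigError(
                f"kcal anchor set infeasible: solved level for region {r} "
                f"is non-positive ({v:.1f} kcal/person/day)"
            )
    return anchors


def _growth_rates_from_multiplier(target_mult: float, weights: pd.Series,
                                  dispersion: pd.Series, n_years: int) -> pd.Series:
    """Per-commodity annual growth rates whose value-weighted cumulative
    multiplier equals ``target_mult`` exactly."""
    raw = target_mult * (1.0 + dispersion)
    raw = raw * (target_mult / float((weights * raw).sum()))
    return raw ** (1.0 / n_years) - 1.0


def _recentred_shock(endpoint: float, weights: pd.Series,
                     dispersion: pd.Series) -> pd.Series:
    raw = endpoint + dispersion
    return raw + (endpoint - float((weights * raw).sum()))


def build_world(seed: int, n_subregions: int = 8, n_commodities: int = 7,
                horizon: int = DEFAULT_HORIZON) -> WorldConfig:
    """Generate a seeded synthetic world whose base year clears all markets.

    ``n_subregions`` counts model regions including the North-Africa-&-West-
    Asia reporting aggregate (default 8 -> 7 leaf regions); ``n_commodities``
    selects the first n of the seven reporting commodity groups.  The same
    seed always yields a byte-identical world.
    """
    if n_subregions < 5:
        raise WorldConfigError("n_subregions must be at least 5")
    if n_subregions < 8:
        raise WorldConfigError(
            "n_subregions below 8 cannot include the five African sub-regions "
            "plus the other-developing and developed aggregates"
        )
    if not (4 <= n_commodities <= len(COMMODITY_GROUPS)):
        raise WorldConfigError(
            f"n_commodities must be in [4, {len(COMMODITY_GROUPS)}]"
        )
    if horizon <= BASE_YEAR:
        raise WorldConfigError("horizon must lie beyond the 2010 base year")

    rng = np.random.default_rng(seed)
    groups = list(COMMODITY_GROUPS[:n_commodities])
    leaves = list(LEAF_REGIONS)

    regions = {}
    for rid in list(LEAF_REGIONS) + list(geo.AGGREGATES):
        regions[rid] = Geography(rid, REGION_NAMES[rid], geo.PARENTS[rid],
                                 FOOD_VA_SHARES.get(rid, 0.1))
    commodities = {g: Commodity(g, g, KCAL_PER_KG[g]) for g in groups}

    macro = pd.DataFrame(
        {r: MACRO_ANCHORS[r] for r in leaves},
        index=["pop_2010", "pop_2020", "pop_2030", "gdp_2010", "gdp_2020", "gdp_2030"],
    ).T

    # demand side: kcal anchors -> 2010 consumption in Mt
    kcal_anchor = _solve_kcal_anchors()
    diet = _jitter(rng, DIET_SHARES[groups], 0.03)
    diet = diet.div(diet.sum(axis=1), axis=0)
    kcal_per_kg = pd.Series({g: KCAL_PER_KG[g] for g in groups})
    consumption = pd.DataFrame(index=leaves, columns=groups, dtype=float)
    for r in leaves:
        total_kcal_yr = kcal_anchor[r] * macro.loc[r, "pop_2010"] * 1e6 * 365.0
        consumption.loc[r] = (total_kcal_yr * diet.loc[r] / kcal_per_kg) / 1e9

    # supply side: world supply = world demand, allocated by production shares
    shares = _jitter(rng, PRODUCTION_SHARES[groups], 0.03)
    shares = shares.div(shares.sum(axis=0), axis=1)
    production = shares.mul(consumption.sum(axis=0), axis=1)

    prices = pd.Series(BASE_PRICES)[groups] * np.exp(rng.normal(0.0, 0.05, len(groups)))
    margins = pd.DataFrame(
        {g: {r: MARGINS[r] for r in leaves} for g in groups}
    ).loc[leaves] * np.exp(rng.normal(0.0, 0.03, (len(leaves), len(groups))))
    margins = margins.clip(upper=0.85)

    supply_e = pd.DataFrame(
        {g: [SUPPLY_PRICE_ELASTICITIES[g]] * len(leaves) for g in groups},
        index=leaves)
    supply_e *= np.exp(rng.normal(0.0, 0.05, supply_e.shape))
    demand_e = pd.DataFrame(DEMAND_PRICE_ELASTICITY, index=leaves, columns=groups)
    demand_e *= np.exp(rng.normal(0.0, 0.05, demand_e.shape))
    income_e = pd.DataFrame(index=leaves, columns=groups, dtype=float)
    for r in leaves:
        cls = "dev" if r == DEV else ("odv" if r == ODV else "africa")
        income_e.loc[r] = INCOME_ELASTICITIES[cls][groups]

    # intrinsic productivity growth calibrated to the NoCC aggregates
    n_years = horizon - BASE_YEAR
    value = production * prices
    growth = pd.DataFrame(index=leaves, columns=groups, dtype=float)
    africa_leaves = list(geo.AFRICAN_SUBREGIONS)
    for r in africa_leaves:
        w = value.loc[r] / value.loc[r].sum()
        disp = pd.Series(rng.uniform(-0.05, 0.05, len(groups)), index=groups)
        growth.loc[r] = _growth_rates_from_multiplier(
            PRODUCTIVITY_MULT_AFRICA, w, disp, n_years)
    # other-developing multiplier solved so the developing aggregate hits its target
    w_afr = float(value.loc[africa_leaves].to_numpy().sum())
    w_odv = float(value.loc[ODV].sum())
    mult_odv = (PRODUCTIVITY_MULT_DEVELOPING * (w_afr + w_odv)
                - PRODUCTIVITY_MULT_AFRICA * w_afr) / w_odv
    for r, mult in ((ODV, mult_odv), (DEV, PRODUCTIVITY_MULT_DEVELOPED)):
        w = value.loc[r] / value.loc[r].sum()
        disp = pd.Series(rng.uniform(-0.05, 0.05, len(groups)), index=groups)
        growth.loc[r] = _growth_rates_from_multiplier(mult, w, disp, n_years)

    # climate-shock 2030 endpoints with per-commodity dispersion
    shock = pd.DataFrame(index=leaves, columns=groups, dtype=float)
    for r in africa_leaves:
        w = value.loc[r] / value.loc[r].sum()
        disp = pd.Series(rng.uniform(-CC_COMMODITY_DISPERSION,
                                     CC_COMMODITY_DISPERSION, len(groups)), index=groups)
        shock.loc[r] = _recentred_shock(CC_SHOCK_AFRICA, w, disp)
    e_odv = (CC_SHOCK_DEVELOPING * (w_afr + w_odv)
             - CC_SHOCK_AFRICA * w_afr) / w_odv
    w_dev = float(value.loc[DEV].sum())
    e_dev = (CC_SHOCK_WORLD * (w_afr + w_odv + w_dev)
             - CC_SHOCK_DEVELOPING * (w_afr + w_odv)) / w_dev
    for r, endpoint in ((ODV, e_odv), (DEV, e_dev)):
        w = value.loc[r] / value.loc[r].sum()
        disp = pd.Series(rng.uniform(-CC_COMMODITY_DISPERSION,
                                     CC_COMMODITY_DISPERSION, len(groups)), index=groups)
        shock.loc[r] = _recentred_shock(endpoint, w, disp)

    world = WorldConfig(
        regions=regions,
        commodities=commodities,
        base_year=BASE_YEAR,
        horizon=horizon,
        production=production,
        consumption=consumption,
        prices=prices,
        margins=margins,
        elasticities=ElasticityBlock(supply_e, demand_e, income_e),
        intrinsic_yield_growth=growth,
        cc_shock_2030=shock,
        macro_anchors=macro,
        seed=seed,
    )

    kcal_afr = world.kcal_per_capita(AFR)
    if abs(kcal_afr / KCAL_TARGET_AFRICA - 1.0) > 0.05:
        raise WorldConfigError(
            f"Africa 2010 kcal anchor unreachable: got {kcal_afr:.0f}"
        )
    return world


def validate_world(world: WorldConfig) -> ValidationReport:
    """Check every structural invariant; never raises."""
    v: list[str] = []
    v.extend(geo.validate_hierarchy(world.regions))

    for c in world.commodity_ids:
        if world.prices[c] <= 0:
            v.append(f"non-positive world price for {c}")
        net = float(world.production[c].sum() - world.consumption[c].sum())
        rel = abs(net) / float(world.production[c].sum())
        if rel >= 1e-10:
            v.append(f"base year does not clear for {c}: relative residual {rel:.2e}")

    for r in world.leaf_regions:
        for c in world.commodity_ids:
            if world.production.at[r, c] <= 0:
                v.append(f"non-positive production for {r}/{c}")
            if world.consumption.at[r, c] <= 0:
                v.append(f"non-positive consumption for {r}/{c}")
            m = world.margins.at[r, c]
            if not (0.0 <= m < 0.9):
                v.append(f"margin out of range [0, 0.9) for {r}/{c}: {m:.3f}")
            es = world.elasticities.supply_price.at[r, c]
            ed = world.elasticities.demand_price.at[r, c]
            ey = world.elasticities.demand_income.at[r, c]
            if es < 0:
                v.append(f"negative supply elasticity for {r}/{c}")
            if not (ed < 0 and abs(ed) <= 2):
                v.append(f"demand price elasticity out of range for {r}/{c}: {ed:.3f}")
            if not (-0.5 <= ey <= 1.5):
                v.append(f"income elasticity out of range for {r}/{c}: {ey:.3f}")
            s = world.cc_shock_2030.at[r, c]
            if not (0.5 < s <= 1.1):
                v.append(f"CC shock endpoint out of (0.5, 1.1] for {r}/{c}: {s:.3f}")

    for r, g in world.regions.items():
        if not (0.0 < g.food_va_share < 0.8):
            v.append(f"food value-added share out of (0, 0.8) for {r}")
    return ValidationReport(v)
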