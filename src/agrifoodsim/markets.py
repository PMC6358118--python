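"""Constant-elasticity multi-market partial equilibrium with margins.

Each commodity has a single world price; regions trade their supply-demand
residual frictionlessly apart from marketing margins, which are split
half-and-half into a producer-side and a consumer-side wedge.  Supply and
demand are constant-elasticity in the respective wedge-adjusted prices, and
world prices are solved each year so global supply equals global demand per
commodity (per-commodity Brent bisection in log price when cross-price
terms are off, damped Newton on the log-price vector otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .world import WorldConfig


class SolverError(RuntimeError):
    pass


@dataclass
class YearDrivers:
    """Everything exogenous to the within-year price solve."""

    year: int
    income_ratio: pd.Series        # per-capita income / base, by leaf region
    population_ratio: pd.Series    # population / base, by leaf region
    productivity: pd.DataFrame     # g(t) * tau * s, leaf region x commodity
    margins: pd.DataFrame          # current wedge fraction, leaf x commodity


@dataclass
class MarketState:
    year: int
    world_price: pd.Series         # USD/t per commodity
    supply: pd.DataFrame           # Mt, leaf region x commodity
    demand: pd.DataFrame           # Mt, leaf region x commodity
    margins: pd.DataFrame
    residuals: pd.Series           # relative clearing residual per commodity


@dataclass
class EquilibriumSolution:
    states: dict[int, MarketState] = field(default_factory=dict)

    def state(self, year: int) -> MarketState:
        return self.states[int(year)]

    @property
    def years(self) -> list[int]:
        return sorted(self.states)

    def worst_residual(self) -> float:
        return max(float(s.residuals.max()) for s in self.states.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for y in self.years:
            s = self.states[y]
            for r in s.supply.index:
                for c in s.supply.columns:
                    rows.append((y, c, r, float(s.world_price[c]),
                                 float(s.supply.at[r, c]), float(s.demand.at[r, c]),
                                 float(s.supply.at[r, c] - s.demand.at[r, c])))
        return pd.DataFrame(rows, columns=["year", "commodity", "region",
                                           "price", "supply", "demand", "net_trade"])


def producer_price_ratio(world: WorldConfig, price_ratio: pd.Series,
                         margins: pd.DataFrame) -> pd.DataFrame:
    """(P (1 - m/2)) / (P0 (1 - m0/2)) per region x commodity."""
    base = 1.0 - world.margins / 2.0
    cur = 1.0 - margins / 2.0
    return (cur / base).mul(price_ratio, axis=1)


def consumer_price_ratio(world: WorldConfig, price_ratio: pd.Series,
                         margins: pd.DataFrame) -> pd.DataFrame:
    base = 1.0 + world.margins / 2.0
    cur = 1.0 + margins / 2.0
    return (cur / base).mul(price_ratio, axis=1)


def supply(world: WorldConfig, drivers: YearDrivers,
           price_ratio: pd.Series) -> pd.DataFrame:
    """Regional supply, Mt: base quantity times producer-price response times
    productivity (intrinsic growth x TFP x climate shock)."""
    pr = producer_price_ratio(world, price_ratio, drivers.margins)
    return (world.production
            * pr.pow(world.elasticities.supply_price)
            * drivers.productivity)


def demand(world: WorldConfig, drivers: YearDrivers,
           price_ratio: pd.Series,
           cross: Optional[dict[str, pd.DataFrame]] = None) -> pd.DataFrame:
    """Regional demand, Mt: base quantity times consumer-price, income, and
    population responses (population elasticity is one)."""
    cr = consumer_price_ratio(world, price_ratio, drivers.margins)
    q = (world.consumption
         * cr.pow(world.elasticities.demand_price)
         * pd.DataFrame(
             np.power.outer(drivers.income_ratio[world.leaf_regions].to_numpy(),
                            np.ones(len(world.commodity_ids))),
             index=world.leaf_regions, columns=world.commodity_ids)
         .pow(world.elasticities.demand_income)
         .mul(drivers.population_ratio, axis=0))
    if cross:
        for r, mat in cross.items():
            term = np.ones(len(world.commodity_ids))
            lp = np.log(price_ratio.to_numpy())
            term = np.exp(mat.to_numpy() @ lp)
            q.loc[r] = q.loc[r] * term
    return q


def _excess_log(world: WorldConfig, drivers: YearDrivers, logp: np.ndarray,
                cross: Optional[dict[str, pd.DataFrame]]) -> np.ndarray:
    ratio = pd.Series(np.exp(logp), index=world.commodity_ids)
    s = supply(world, drivers, ratio).sum(axis=0).to_numpy()
    d = demand(world, drivers, ratio, cross).sum(axis=0).to_numpy()
    return np.log(s) - np.log(d)


def solve_year(world: WorldConfig, drivers: YearDrivers,
               init_price_ratio: Optional[pd.Series] = None,
               cross: Optional[dict[str, pd.DataFrame]] = None,
               tol: float = 1e-10, max_iter: int = 200) -> MarketState:
    """Find world prices that clear every commodity market in one year.

    Without cross-price terms the markets separate and each log price is
    solved by Brent's method (log excess supply is strictly increasing in
    own log price).  With cross-price terms a damped Newton iteration on the
    log-price vector is used, halving the step while the residual worsens.
    Deterministic for given inputs.
    """
    cids = world.commodity_ids
    logp0 = (np.log(init_price_ratio[cids].to_numpy())
             if init_price_ratio is not None else np.zeros(len(cids)))

    if not cross:
        # markets separate: per-commodity scalar root find on numpy columns
        leaf = world.leaf_regions
        ppr0 = producer_price_ratio(world, pd.Series(1.0, index=cids),
                                    drivers.margins).to_numpy()
        cpr0 = consumer_price_ratio(world, pd.Series(1.0, index=cids),
                                    drivers.margins).to_numpy()
        es = world.elasticities.supply_price.to_numpy()
        ed = world.elasticities.demand_price.to_numpy()
        ey = world.elasticities.demand_income.to_numpy()
        s_base = (world.production.to_numpy() * drivers.productivity.to_numpy())
        inc = drivers.income_ratio[leaf].to_numpy()[:, None]
        d_base = (world.consumption.to_numpy() * np.power(inc, ey)
                  * drivers.population_ratio[leaf].to_numpy()[:, None])
        logp = np.empty(len(cids))
        for j in range(len(cids)):
            sj, dj = s_base[:, j], d_base[:, j]
            pj, cj, esj, edj = ppr0[:, j], cpr0[:, j], es[:, j], ed[:, j]

            def f(x: float) -> float:
                pr = np.exp(x)
                return (np.log(np.sum(sj * (pj * pr) ** esj))
                        - np.log(np.sum(dj * (cj * pr) ** edj)))

            lo, hi = logp0[j] - 1.0, logp0[j] + 1.0
            for _ in range(60):
                if f(lo) < 0:
                    break
                lo -= 1.0
            for _ in range(60):
                if f(hi) > 0:
                    break
                hi += 1.0
            if not (f(lo) < 0 < f(hi)):
                raise SolverError(f"cannot bracket price for {cids[j]}")
            logp[j] = optimize.brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    else:
        logp = logp0.copy()
        F = _excess_log(world, drivers, logp, cross)
        for it in range(max_iter):
            if np.max(np.abs(F)) < tol:
                break
            J = np.empty((len(cids), len(cids)))
            h = 1e-7
            for j in range(len(cids)):
                pert = logp.copy()
                pert[j] += h
                J[:, j] = (_excess_log(world, drivers, pert, cross) - F) / h
            step = np.linalg.solve(J, -F)
            lam = 1.0
            for _ in range(40):
                trial = logp + lam * step
                Ft = _excess_log(world, drivers, trial, cross)
                if np.max(np.abs(Ft)) < np.max(np.abs(F)):
                    logp, F = trial, Ft
                    break
                lam *= 0.5
            else:
                raise SolverError("Newton damping failed to reduce the residual")
        else:
            worst = cids[int(np.argmax(np.abs(F)))]
            raise SolverError(
                f"no convergence after {max_iter} iterations; worst residual "
                f"{np.max(np.abs(F)):.2e} on {worst}")

    ratio = pd.Series(np.exp(logp), index=cids)
    s = supply(world, drivers, ratio)
    d = demand(world, drivers, ratio, cross)
    resid = (s.sum(axis=0) - d.sum(axis=0)).abs() / s.sum(axis=0)
    if float(resid.max()) >= 1e-6:
        raise SolverError(
            f"clearing residual contract violated: {float(resid.max()):.2e}")
    return MarketState(drivers.year, ratio * world.prices, s, d,
                       drivers.margins.copy(), resid)


def price_index(solution: EquilibriumSolution, world: WorldConfig, group: str,
                year: int, base_year: Optional[int] = None) -> float:
    """Consumption-weighted world-price index for a commodity group
    (base year = 1.0)."""
    base_year = world.base_year if base_year is None else base_year
    members = [c for c, k in world.commodities.items() if k.group == group]
    if group == "all":
        members = world.commodity_ids
    if not members:
        raise ValueError(f"empty commodity group {group!r}")
    w = world.consumption[members].sum(axis=0)
    w = w / w.sum()
    p_now = solution.state(year).world_price[members]
    p_base = solution.state(base_year).world_price[members]
    return float((w * (p_now / p_base)).sum())
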