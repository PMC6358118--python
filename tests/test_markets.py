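"""Partial-equilibrium market core: closed forms, clearing, statics."""

import numpy as np
import pandas as pd
import pytest

import agrifoodsim as afs
from agrifoodsim.markets import (EquilibriumSolution, YearDrivers, demand,
                                 price_index, solve_year, supply)
from agrifoodsim.geography import DEV


def base_drivers(world, year=2010):
    leaves = world.leaf_regions
    prod = pd.DataFrame(1.0, index=leaves, columns=world.commodity_ids)
    return YearDrivers(year, pd.Series(1.0, index=leaves),
                       pd.Series(1.0, index=leaves), prod, world.margins.copy())


def test_base_year_is_fixed_point(world):
    state = solve_year(world, base_drivers(world))
    assert np.allclose(state.world_price.to_numpy(), world.prices.to_numpy(),
                       rtol=1e-9)
    assert np.allclose(state.supply.to_numpy(), world.production.to_numpy(),
                       rtol=1e-9)


def test_supply_demand_closed_forms(world):
    d = base_drivers(world)
    c = world.commodity_ids[0]
    # supply elasticity 0.5, producer price x4 -> quantity x2
    w2 = afs.WorldConfig.from_json(world.to_json())
    w2.elasticities.supply_price.loc[:, :] = 0.5
    ratio = pd.Series(1.0, index=w2.commodity_ids)
    ratio[c] = 4.0
    q = supply(w2, base_drivers(w2), ratio)
    assert np.allclose(q[c], 2.0 * w2.production[c], rtol=1e-12)
    # demand elasticity -0.5, consumer price x4 -> quantity x0.5
    w2.elasticities.demand_price.loc[:, :] = -0.5
    qd = demand(w2, base_drivers(w2), ratio)
    assert np.allclose(qd[c], 0.5 * w2.consumption[c], rtol=1e-12)
    # population x2 at fixed prices and income -> demand x2
    d2 = base_drivers(w2)
    d2.population_ratio[:] = 2.0
    qd2 = demand(w2, d2, pd.Series(1.0, index=w2.commodity_ids))
    assert np.allclose(qd2.to_numpy(), 2.0 * w2.consumption.to_numpy(), rtol=1e-12)


def test_negative_supply_shock_applies_multiplicatively(world):
    d = base_drivers(world)
    d.productivity.loc[:, :] = 0.93
    q = supply(world, d, pd.Series(1.0, index=world.commodity_ids))
    assert np.allclose(q.to_numpy(), 0.93 * world.production.to_numpy(), rtol=1e-12)


def test_one_market_closed_form_equilibrium(world):
    """One region, one commodity, eps_s=1, eps_d=-1, demand shifter 1.21:
    the equilibrium price rises by exactly sqrt(1.21) = 1.1."""
    w = afs.WorldConfig.from_json(world.to_json())
    c = w.commodity_ids[0]
    w.elasticities.supply_price.loc[:, c] = 1.0
    w.elasticities.demand_price.loc[:, c] = -1.0
    w.elasticities.demand_income.loc[:, c] = 1.0
    d = base_drivers(w)
    d.income_ratio[:] = 1.21  # demand shifter x1.21 through unit elasticity
    state = solve_year(w, d)
    assert state.world_price[c] / w.prices[c] == pytest.approx(1.1, rel=1e-9)


def test_market_clearing_residuals(bundles):
    for b in bundles.values():
        assert b.solution.worst_residual() < 1e-6


def test_homogeneity_in_base_prices(world):
    """Doubling all base prices leaves equilibrium quantities unchanged —
    only relative prices matter."""
    w2 = afs.WorldConfig.from_json(world.to_json())
    w2.prices = w2.prices * 2.0
    d1 = base_drivers(world)
    d1.income_ratio[:] = 1.3
    d2 = base_drivers(w2)
    d2.income_ratio[:] = 1.3
    s1 = solve_year(world, d1)
    s2 = solve_year(w2, d2)
    assert np.allclose(s1.supply.to_numpy(), s2.supply.to_numpy(), rtol=1e-9)
    assert np.allclose(s2.world_price / w2.prices, s1.world_price / world.prices,
                       rtol=1e-9)


@pytest.mark.parametrize("seed", [2, 5])
def test_price_rises_under_negative_supply_shock(seed):
    """Comparative statics on random worlds: an adverse productivity shock
    with unchanged demand strictly raises every equilibrium price."""
    w = afs.build_world(seed)
    d0 = base_drivers(w)
    base = solve_year(w, d0)
    d1 = base_drivers(w)
    d1.productivity.loc[:, :] = 0.9
    shocked = solve_year(w, d1)
    assert (shocked.world_price.to_numpy() > base.world_price.to_numpy()).all()


def test_margin_reduction_moves_both_wedge_prices(world):
    """At a fixed world price, cutting the margin lowers the consumer price
    and raises the producer price simultaneously."""
    from agrifoodsim.markets import consumer_price_ratio, producer_price_ratio
    ones = pd.Series(1.0, index=world.commodity_ids)
    reduced = world.margins * 0.8
    cons = consumer_price_ratio(world, ones, reduced)
    prod = producer_price_ratio(world, ones, reduced)
    assert (cons.to_numpy() < 1.0).all()
    assert (prod.to_numpy() > 1.0).all()


def test_walras_conservation_at_solution(bundles, world):
    state = bundles["CC"].solution.state(2030)
    for c in world.commodity_ids:
        prod = state.supply[c].sum()
        cons = state.demand[c].sum()
        assert abs(prod - cons) / prod < 1e-6


def test_cross_price_solver_matches_diagonal_when_zero(world):
    zero_cross = {r: pd.DataFrame(0.0, index=world.commodity_ids,
                                  columns=world.commodity_ids)
                  for r in world.leaf_regions}
    d = base_drivers(world)
    d.income_ratio[:] = 1.2
    diag = solve_year(world, d)
    full = solve_year(world, base_drivers(world) if False else d, cross=zero_cross)
    assert np.allclose(diag.world_price.to_numpy(), full.world_price.to_numpy(),
                       rtol=1e-7)


def test_cross_price_terms_shift_equilibrium(world):
    """A small substitute cross-price term raises demand for a commodity
    when its substitute's price rises, shifting the solved prices."""
    cids = world.commodity_ids
    mat = pd.DataFrame(0.0, index=cids, columns=cids)
    mat.loc["cereals", "roots_tubers"] = 0.1
    cross = {r: mat for r in world.leaf_regions}
    d = base_drivers(world)
    d.productivity["roots_tubers"] = 0.8  # scarce substitute
    no_cross = solve_year(world, d)
    with_cross = solve_year(world, d, cross=cross)
    assert with_cross.world_price["cereals"] > no_cross.world_price["cereals"]


def test_price_index_identities(bundles, world):
    sol = bundles["NoCC"].solution
    assert price_index(sol, world, "cereals", 2010) == pytest.approx(1.0)
    # single-commodity group: index equals the raw price ratio
    ratio = (sol.state(2030).world_price["sugar"]
             / sol.state(2010).world_price["sugar"])
    assert price_index(sol, world, "sugar", 2030) == pytest.approx(ratio)
    with pytest.raises(ValueError):
        price_index(sol, world, "dairy", 2030)


def test_nocc_price_band(bundles, world):
    """Calibration-band check: 2030 NoCC price indices lie within +10-30 %."""
    sol = bundles["NoCC"].solution
    for g in world.commodity_ids:
        idx = price_index(sol, world, g, 2030)
        assert 1.10 <= idx <= 1.30, (g, idx)
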