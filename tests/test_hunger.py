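"""Kcal availability and hunger-prevalence indicators."""

import numpy as np
import pandas as pd
import pytest

import agrifoodsim as afs
from agrifoodsim.geography import AFR, CAF, EAF, NAF, SAF, WAF
from agrifoodsim.hunger import (HungerConfigError, HungerCurveParams,
                                aggregate_indicators, hunger_share,
                                indicators_from_kcal, kcal_availability,
                                kcal_for_share, population_at_risk,
                                threshold_report)


def test_kcal_unit_conversion_identity():
    # 0.365 Mt at 2500 kcal/kg for 1 million people is exactly 2500 kcal/day
    demand = pd.Series({"x": 0.365})
    density = pd.Series({"x": 2500.0})
    assert kcal_availability(demand, density, 1.0) == pytest.approx(2500.0)


def test_doubling_population_halves_kcal():
    demand = pd.Series({"x": 1.0})
    density = pd.Series({"x": 3400.0})
    one = kcal_availability(demand, density, 10.0)
    two = kcal_availability(demand, density, 20.0)
    assert two == pytest.approx(one / 2.0)


def test_calibrated_2010_shares(world, calib):
    curve = calib.hunger_curve
    assert hunger_share(world.kcal_per_capita(EAF), curve) == pytest.approx(0.35, abs=1e-9)
    assert hunger_share(world.kcal_per_capita(CAF), curve) == pytest.approx(0.41, abs=1e-9)
    # Africa aggregate: population-weighted 2010 share is 21 %
    pops = world.macro_anchors["pop_2010"]
    shares = {r: hunger_share(world.kcal_per_capita(r), curve)
              for r in (NAF, WAF, EAF, CAF, SAF)}
    agg = sum(pops[r] * s for r, s in shares.items()) / pops[[*shares]].sum()
    assert agg == pytest.approx(0.21, abs=1e-6)


def test_share_saturates_at_floor(calib):
    assert hunger_share(10000.0, calib.hunger_curve) == calib.hunger_curve.floor


def test_share_monotone_decreasing_in_kcal(calib):
    grid = np.linspace(1500, 4500, 200)
    shares = [hunger_share(k, calib.hunger_curve) for k in grid]
    assert all(b <= a + 1e-12 for a, b in zip(shares, shares[1:]))


def test_inverse_round_trip(calib):
    curve = calib.hunger_curve
    for share in (0.40, 0.30, 0.21, 0.10, 0.055):
        k = kcal_for_share(share, curve)
        assert hunger_share(k, curve) == pytest.approx(share, abs=1e-10)


def test_non_monotone_anchors_rejected():
    with pytest.raises(HungerConfigError):
        HungerCurveParams([(0.9, 0.3), (1.0, 0.35)])
    with pytest.raises(HungerConfigError):
        HungerCurveParams([(0.9, 0.3), (0.9, 0.2)])


def test_population_at_risk_arithmetic():
    assert population_at_risk(0.0, 1538.0) == 0.0
    assert population_at_risk(0.10, 1538.0) == pytest.approx(153.8)
    with pytest.raises(HungerConfigError):
        population_at_risk(1.2, 100.0)


def test_share_millions_consistency(bundles):
    for b in bundles.values():
        for ind in b.hunger.values():
            pop = ind.millions_at_risk / ind.share_at_risk
            assert np.allclose(ind.millions_at_risk,
                               ind.share_at_risk * pop, rtol=1e-12)


def test_aggregate_sums_millions_never_averages_shares(bundles):
    b = bundles["CC"]
    parts = [b.hunger[r] for r in (WAF, EAF, CAF, SAF)]
    agg = aggregate_indicators("SSA", parts)
    manual = np.sum([p.millions_at_risk for p in parts], axis=0)
    assert np.allclose(agg.millions_at_risk, manual, rtol=1e-12)
    # share of the aggregate is millions over population, not a mean of shares
    mean_share = np.mean([p.share_at_risk for p in parts], axis=0)
    assert not np.allclose(agg.share_at_risk, mean_share)


def test_threshold_inclusive_boundary():
    years = np.array([2030])
    curve_pop = np.array([100.0])
    at = indicators_from_kcal("A", "X", years, np.array([3000.0]), curve_pop,
                              HungerCurveParams([(0.9, 0.35), (1.5, 0.02)]))
    at.share_at_risk[:] = 0.05  # exactly at the threshold
    below = indicators_from_kcal("B", "X", years, np.array([3000.0]), curve_pop,
                                 HungerCurveParams([(0.9, 0.35), (1.5, 0.02)]))
    below.share_at_risk[:] = 0.04
    above = indicators_from_kcal("C", "X", years, np.array([3000.0]), curve_pop,
                                 HungerCurveParams([(0.9, 0.35), (1.5, 0.02)]))
    above.share_at_risk[:] = 0.06
    rep = threshold_report({"A": at, "B": below, "C": above}, 2030)
    assert rep["meeting"] == ["A", "B"]
    assert rep["count"] == 2


def test_monotone_chain_more_tfp_less_hunger(world, calib, bundles):
    """COMP differs from CC only by larger productivity-side interventions:
    kcal is weakly higher and the share at risk weakly lower everywhere."""
    comp, cc = bundles["COMP"], bundles["CC"]
    for r in world.leaf_regions:
        assert (comp.hunger[r].kcal_pc >= cc.hunger[r].kcal_pc - 1e-9).all()
        assert (comp.hunger[r].share_at_risk
                <= cc.hunger[r].share_at_risk + 1e-12).all()
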