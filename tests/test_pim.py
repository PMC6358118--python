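"""Perpetual-inventory knowledge stocks: closed forms and inverse costing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agrifoodsim.pim import (InvestmentStream, PimParams, PimError,
                             accumulate_stock, comp_ramp_profile,
                             default_params, required_investment, tfp_growth,
                             trapezoid_lags)

YEARS = np.arange(2010, 2031)


def stream(amounts, region="SSA", inst="CGIAR"):
    return InvestmentStream(region, inst, "R&D", YEARS[:len(amounts)],
                            np.asarray(amounts, dtype=float))


def test_single_pulse_without_decay_raises_stock_by_pulse():
    """With (near) zero decay and a one-year lag, a unit pulse lifts the
    stock by one unit permanently."""
    delta = 1e-12
    p = PimParams("applied", delta, np.array([1.0]), 0.2)
    amounts = np.zeros(len(YEARS))
    amounts[5] = 1.0
    base = accumulate_stock(stream(np.zeros(len(YEARS))), p, K0=0.0)
    pulsed = accumulate_stock(stream(amounts), p, K0=0.0)
    diff = pulsed.levels - base.levels
    assert diff[4] == pytest.approx(0.0, abs=1e-9)
    assert diff[5] == pytest.approx(1.0, abs=1e-9)
    assert diff[-1] == pytest.approx(1.0, abs=1e-6)


def test_constant_investment_converges_to_I_over_delta():
    """Geometric-series closed form: K -> I/delta, checked by brute-force
    iteration over 500 years."""
    years = np.arange(2000, 2501)
    p = PimParams("applied", 0.08, trapezoid_lags(6, 3), 0.2)
    s = InvestmentStream("SSA", "CGIAR", "R&D", years, np.full(len(years), 2.5))
    K = accumulate_stock(s, p, K0=0.0)
    assert K.levels[-1] == pytest.approx(2.5 / 0.08, rel=1e-9)


def test_spillover_symmetry_full_sharing():
    """With sigma = 1 both ways and equal parameters, stocks are identical
    regardless of which region receives the investment."""
    p = PimParams("applied", 0.1, trapezoid_lags(4, 2), 0.2, spillover_in=1.0)
    inv = np.linspace(1.0, 3.0, len(YEARS))
    zero = np.zeros(len(YEARS))
    a_gets = accumulate_stock(stream(inv, "A"), p, foreign=[stream(zero, "B")])
    b_gets = accumulate_stock(stream(zero, "A"), p, foreign=[stream(inv, "B")])
    assert np.allclose(a_gets.levels, b_gets.levels, rtol=1e-12)


def test_zero_investment_decays_geometrically():
    p = PimParams("applied", 0.15, np.array([1.0]), 0.2)
    K = accumulate_stock(stream(np.zeros(len(YEARS))), p, K0=10.0)
    expected = 10.0 * (1.0 - 0.15) ** np.arange(1, len(YEARS) + 1)
    assert np.allclose(K.levels, expected, rtol=1e-12)


def test_tfp_identities():
    p = default_params("CGIAR")
    from agrifoodsim.pim import KnowledgeStock
    const = KnowledgeStock("SSA", "CGIAR", YEARS, np.full(len(YEARS), 4.0))
    assert np.allclose(tfp_growth(const, p), 1.0)
    p_unit = PimParams("basic", 0.1, trapezoid_lags(10, 5), 1.0)
    doubling = KnowledgeStock("SSA", "CGIAR", YEARS[:2], np.array([1.0, 2.0]))
    assert tfp_growth(doubling, p_unit)[-1] == pytest.approx(2.0)


def test_tfp_multiplier_converges_to_one_at_steady_state():
    years = np.arange(2000, 2301)
    p = PimParams("applied", 0.1, trapezoid_lags(6, 3), 0.3)
    s = InvestmentStream("SSA", "CGIAR", "R&D", years, np.full(len(years), 1.0))
    K = accumulate_stock(s, p)
    mult = tfp_growth(K, p)
    # annual growth at the end of the horizon is negligible
    assert mult[-1] / mult[-2] == pytest.approx(1.0, abs=1e-10)


def test_monotonicity_larger_streams_larger_stocks():
    p = default_params("NARS")
    lo = accumulate_stock(stream(np.full(len(YEARS), 1.0), inst="NARS"), p)
    hi = accumulate_stock(stream(np.full(len(YEARS), 1.5), inst="NARS"), p)
    assert (hi.levels >= lo.levels).all()
    assert tfp_growth(hi, p)[-1] >= tfp_growth(lo, p)[-1] - 1e-12


def test_required_investment_identity_target():
    p = default_params("CGIAR")
    base = stream(np.full(len(YEARS), 1.0) * 1.05 ** np.arange(len(YEARS)))
    add, scale = required_investment(1.0, base, p)
    assert scale == 0.0
    assert np.allclose(add.amounts, 0.0)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.floats(0.5, 30.0))
def test_required_investment_round_trip(true_scale):
    """Inverse consistency: the uplift produced by a known additional stream
    is recovered by the solver to within 1e-6 relative scale."""
    p = default_params("CGIAR")
    base = stream(0.5 * 1.06 ** np.arange(len(YEARS)))
    profile = comp_ramp_profile(YEARS)
    known = base.scaled_add(
        InvestmentStream("SSA", "CGIAR", "R&D", YEARS, profile), true_scale)
    target = (tfp_growth(accumulate_stock(known, p), p)[-1]
              / tfp_growth(accumulate_stock(base, p), p)[-1])
    _, recovered = required_investment(target, base, p, profile=profile)
    assert recovered == pytest.approx(true_scale, rel=1e-4)


def test_required_investment_infeasible_target():
    p = default_params("CGIAR")
    base = stream(np.full(len(YEARS), 1.0))
    with pytest.raises(PimError, match="infeasible"):
        required_investment(0.9, base, p)


def test_invalid_streams_and_params_rejected():
    with pytest.raises(PimError):
        InvestmentStream("SSA", "capital", "R&D", YEARS, np.ones(len(YEARS)))
    with pytest.raises(PimError):
        InvestmentStream("SSA", "CGIAR", "R&D", YEARS, -np.ones(len(YEARS)))
    with pytest.raises(PimError):
        PimParams("basic", 0.5, np.array([1.0]), 0.2)  # decay beyond 0.3
    with pytest.raises(PimError):
        PimParams("basic", 0.1, np.array([0.7, 0.7]), 0.2)  # weights not 1
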