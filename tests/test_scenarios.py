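"""Scenario orchestration: nesting, determinism, comparisons, R&D costing."""

import numpy as np
import pandas as pd
import pytest

import agrifoodsim as afs
from agrifoodsim.geography import AFR
from agrifoodsim.scenarios import (COMP_RND_UPLIFT, ScenarioError, ScenarioSpec,
                                   compare, default_scenarios, run_scenario,
                                   solve_comp_rnd)


def test_nocc_and_cc_identical_before_shocks_phase_in(bundles):
    for y in (2010,):
        p_nocc = bundles["NoCC"].solution.state(y).world_price
        p_cc = bundles["CC"].solution.state(y).world_price
        assert np.allclose(p_nocc.to_numpy(), p_cc.to_numpy(), rtol=1e-12)


def test_null_comp_reproduces_cc_bitwise(world, calib, bundles):
    null = ScenarioSpec("COMP", "CC", {}, None, 0.0)
    b = run_scenario(world, null, calib)
    for y in world.years:
        assert np.array_equal(
            b.solution.state(int(y)).world_price.to_numpy(),
            bundles["CC"].solution.state(int(y)).world_price.to_numpy())


def test_baseline_scenarios_reject_interventions():
    with pytest.raises(ScenarioError):
        ScenarioSpec("NoCC", "NoCC", margin_reduction=0.2)
    with pytest.raises(ScenarioError):
        ScenarioSpec("CC", "CC", rnd_uplift={"SSA": 1.1})
    with pytest.raises(ScenarioError):
        ScenarioSpec("COMP", "CC", start_year=2012)


def test_end_to_end_determinism(world, calib):
    spec = default_scenarios(calib)["CC"]
    b1 = run_scenario(world, spec, calib)
    b2 = run_scenario(world, spec, calib)
    for y in (2015, 2030):
        assert np.array_equal(b1.solution.state(y).world_price.to_numpy(),
                              b2.solution.state(y).world_price.to_numpy())
    assert np.array_equal(b1.hunger[AFR].millions_at_risk,
                          b2.hunger[AFR].millions_at_risk)


def test_compare_self_is_zero_and_antisymmetric(world, bundles):
    same = compare(bundles["CC"], bundles["CC"], world)
    for frame in same.values():
        assert np.allclose(frame.to_numpy(dtype=float), 0.0)
    ab = compare(bundles["COMP"], bundles["CC"], world)
    ba = compare(bundles["CC"], bundles["COMP"], world)
    for key in ab:
        assert np.allclose(ab[key].to_numpy(dtype=float),
                           -ba[key].to_numpy(dtype=float), atol=1e-12)


def test_compare_rejects_mismatched_worlds(world, calib, bundles):
    other_world = afs.build_world(seed=9)
    other_calib = afs.calibrate(other_world)
    spec = default_scenarios(other_calib)["CC"]
    other = run_scenario(other_world, spec, other_calib)
    with pytest.raises(ScenarioError):
        compare(bundles["CC"], other, world)


def test_comp_hunger_delta_negative_for_africa(world, bundles):
    delta = compare(bundles["COMP"], bundles["CC"], world)
    assert delta["hunger_millions"].at[2030, AFR] < 0


def test_comp_rnd_streams_match_printed_averages(world, calib):
    """The inverse PIM costing reproduces the printed additional CGIAR
    streams: 0.67 billion/yr in SSA and 0.74 across developing regions."""
    streams, paths = solve_comp_rnd(world.years, COMP_RND_UPLIFT, calib.etas)
    ssa = streams["SSA"].average(2015, 2030)
    total = sum(s.average(2015, 2030) for s in streams.values())
    assert ssa == pytest.approx(0.67, abs=0.01)
    assert total == pytest.approx(0.74, abs=0.015)
    # uplift paths hit their 2030 targets
    for r, path in paths.items():
        assert path[-1] == pytest.approx(COMP_RND_UPLIFT[r], rel=1e-5)
        assert path[0] == pytest.approx(1.0)


def test_comp_interventions_silent_before_2015(bundles, world):
    comp, cc = bundles["COMP"], bundles["CC"]
    for y in (2010, 2014):
        assert np.allclose(comp.solution.state(y).world_price.to_numpy(),
                           cc.solution.state(y).world_price.to_numpy(),
                           rtol=1e-9)
    assert np.allclose(comp.tfp_uplift.loc[2014].to_numpy(), 1.0, atol=1e-9)


def test_ssa_irrigation_target_consistent_with_printed_table(calib):
    """COMP targets a 30 % irrigated-area increase for SSA relative to the
    2030 baseline area."""
    targets = default_scenarios(calib)["COMP"].capital_targets
    assert targets.increments.at["SSA", "irrigation_expansion"] == pytest.approx(
        0.30 * 12.0)


def test_runtime_three_scenarios_under_two_minutes(world, calib):
    import time
    t0 = time.time()
    afs.run_all(world, calib)
    assert time.time() - t0 < 120.0
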