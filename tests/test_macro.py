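"""Macro trajectories: compounding, income arithmetic, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import agrifoodsim as afs
from agrifoodsim.geography import AFR, SSA, DVG, WLD
from agrifoodsim.macro import (MacroError, aggregate_regions, average_income,
                               geometric_interpolate, project_series,
                               trajectories_from_world, region_trajectory,
                               MacroTrajectory)


def test_compounding_closed_forms():
    assert project_series(1.0, 0.10, 2)[-1] == pytest.approx(1.21, abs=1e-12)
    assert np.allclose(project_series(5.0, 0.0, 10), 5.0)
    # Africa GDP: 2.8 trillion at 5.2 %/yr for 20 years lands near 7.7
    assert project_series(2.8, 0.052, 20)[-1] == pytest.approx(7.7, rel=0.01)


@pytest.mark.parametrize("base, cagr, years", [(0.0, 0.05, 5), (1.0, -1.0, 5),
                                               (1.0, 0.05, -1)])
def test_compounding_domain_errors(base, cagr, years):
    with pytest.raises(MacroError):
        project_series(base, cagr, years)


def test_average_income_reproduces_printed_cells(fixtures):
    t2 = fixtures.macro
    years = np.array([2010])
    world_2010 = MacroTrajectory("WLD", years,
                                 np.array([t2.at["WLD", "pop_2010"]]),
                                 np.array([t2.at["WLD", "gdp_2010"]]))
    assert round(average_income(world_2010, 2010), 1) == 9.8
    africa_2030 = MacroTrajectory("AFR", np.array([2030]),
                                  np.array([t2.at["AFR", "pop_2030"]]),
                                  np.array([t2.at["AFR", "gdp_2030"]]))
    assert round(average_income(africa_2030, 2030), 1) == 5.0


def test_average_income_identity():
    t = MacroTrajectory("X", np.array([2010]), np.array([123.0]),
                        np.array([123.0 * 0.007]))  # gdp = pop * k
    assert average_income(t, 2010) == pytest.approx(7.0, rel=1e-12)


def test_all_printed_income_cells_within_rounding_bounds(fixtures):
    """Printed GDP carries +/- 0.05 trillion of rounding, so printed income
    must lie within the implied bound of recomputed GDP/population."""
    t2 = fixtures.macro
    for region in t2.index:
        for yr in ("2010", "2020", "2030"):
            pop = t2.at[region, f"pop_{yr}"]
            computed = t2.at[region, f"gdp_{yr}"] / pop * 1000.0
            printed = t2.at[region, f"income_{yr}"]
            tol = 1000.0 * 0.05 / pop + 0.05 + 1e-9
            assert abs(computed - printed) <= tol, (region, yr)


def test_income_identity_on_world_trajectories(world):
    trajs = trajectories_from_world(world)
    for r, t in trajs.items():
        for year in (2010, 2019, 2030):
            y = average_income(t, year)
            i = t.index_of(year)
            assert y * t.population[i] / 1000.0 == pytest.approx(
                t.gdp[i], rel=1e-12)


def test_geometric_interpolation_hits_anchors(world):
    trajs = trajectories_from_world(world)
    for r in world.leaf_regions:
        row = world.macro_anchors.loc[r]
        t = trajs[r]
        assert t.population[t.index_of(2020)] == pytest.approx(row["pop_2020"], rel=1e-12)
        assert t.gdp[t.index_of(2030)] == pytest.approx(row["gdp_2030"], rel=1e-12)


def test_aggregation_associativity(world):
    trajs = trajectories_from_world(world)
    ssa = region_trajectory(world, SSA, trajs)
    afr_stepwise = aggregate_regions({**trajs, SSA: ssa}, AFR, ["NAF", SSA])
    afr_oneshot = region_trajectory(world, AFR, trajs)
    assert np.allclose(afr_stepwise.population, afr_oneshot.population, rtol=1e-14)
    assert np.allclose(afr_stepwise.gdp, afr_oneshot.gdp, rtol=1e-14)


def test_single_child_aggregate_identical():
    t = MacroTrajectory("X", np.array([2010, 2011]), np.array([10.0, 11.0]),
                        np.array([1.0, 1.1]))
    agg = aggregate_regions({"X": t}, "AGG", ["X"])
    assert np.array_equal(agg.population, t.population)
    assert np.array_equal(agg.gdp, t.gdp)


def test_missing_child_named_in_error():
    t = MacroTrajectory("X", np.array([2010]), np.array([1.0]), np.array([1.0]))
    with pytest.raises(MacroError, match="Y"):
        aggregate_regions({"X": t}, "AGG", ["X", "Y"])


@settings(deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(1.0, 1e4), st.floats(0.1, 100.0)),
                min_size=2, max_size=6))
def test_aggregate_income_bounded_by_children(pops_gdps):
    """The aggregate's income is a population-weighted mean, so it lies
    between the child minimum and maximum."""
    years = np.array([2010])
    trajs = {f"r{i}": MacroTrajectory(f"r{i}", years, np.array([p]), np.array([g]))
             for i, (p, g) in enumerate(pops_gdps)}
    agg = aggregate_regions(trajs, "AGG", list(trajs))
    incomes = [average_income(t, 2010) for t in trajs.values()]
    y = average_income(agg, 2010)
    assert min(incomes) - 1e-9 <= y <= max(incomes) + 1e-9
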