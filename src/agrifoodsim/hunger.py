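"""Dietary-energy availability and hunger-prevalence indicators.

Food demand is converted to kcal/person/day; the share of the population at
risk of hunger is a monotone-decreasing piecewise log-linear curve in the
ratio of kcal availability to a reference requirement (2400 kcal/day, the
recommended intake of an active young adult female), clipped to a floor —
the exact prevalence relation used by the source modelling system is not
published, so the curve is calibrated to the printed 2010 shares (Africa
21 %, Eastern Africa 35 %, Central Africa 41 %) and is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geography import AFR, CAF, EAF, NAF, SAF, WAF
from .world import WorldConfig

REQUIREMENT_KCAL = 2400.0
MINIMUM_LINE_KCAL = 1800.0  # plotting reference only
HUNGER_THRESHOLD = 0.05

# 2010 calibration shares (printed): aggregate Africa and the two most
# food-insecure sub-regions; Northern/Southern fixed by convention and
# Western solved so the Africa aggregate comes out right.
SHARE_2010 = {AFR: 0.21, EAF: 0.35, CAF: 0.41}
SHARE_2010_CONVENTION = {NAF: 0.05, SAF: 0.06}
FLOOR_SHARE = 0.02
TAIL_ANCHOR = (1.45, 0.02)


class HungerConfigError(ValueError):
    pass


@dataclass
class HungerCurveParams:
    """Anchor pairs (kcal ratio, share) for the prevalence curve."""

    anchors: list[tuple[float, float]]
    floor: float = FLOOR_SHARE
    requirement: float = REQUIREMENT_KCAL

    def __post_init__(self) -> None:
        xs = [a[0] for a in self.anchors]
        ys = [a[1] for a in self.anchors]
        if any(x2 <= x1 for x1, x2 in zip(xs, xs[1:])):
            raise HungerConfigError("anchor kcal ratios must be strictly increasing")
        if any(y2 >= y1 for y1, y2 in zip(ys, ys[1:])):
            raise HungerConfigError(
                "anchor shares must be strictly decreasing in the kcal ratio")
        if self.floor > min(ys):
            raise HungerConfigError("floor must not exceed the smallest anchor share")


@dataclass
class HungerIndicators:
    region_id: str
    scenario: str
    years: np.ndarray
    kcal_pc: np.ndarray
    share_at_risk: np.ndarray
    millions_at_risk: np.ndarray


def kcal_availability(demand_mt: pd.Series, kcal_per_kg: pd.Series,
                      population_millions: float) -> float:
    """kcal/person/day from demand in Mt and population in millions."""
    if population_millions <= 0:
        raise HungerConfigError("population must be positive")
    total_kcal = float((demand_mt * kcal_per_kg).sum()) * 1e9
    return total_kcal / (population_millions * 1e6 * 365.0)


def hunger_share(kcal_pc: float, params: HungerCurveParams) -> float:
    """Share of population at risk, via log-linear interpolation between
    anchors on (log kcal-ratio, log share), clipped to [floor, 1]."""
    if kcal_pc <= 0:
        raise HungerConfigError("kcal availability must be positive")
    x = np.log(kcal_pc / params.requirement)
    xs = np.log([a[0] for a in params.anchors])
    ys = np.log([a[1] for a in params.anchors])
    # linear extrapolation beyond the outermost anchors, then clip
    if x <= xs[0]:
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        ly = ys[0] + slope * (x - xs[0])
    elif x >= xs[-1]:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        ly = ys[-1] + slope * (x - xs[-1])
    else:
        ly = float(np.interp(x, xs, ys))
    return float(np.clip(np.exp(ly), params.floor, 1.0))


def kcal_for_share(share: float, params: HungerCurveParams) -> float:
    """Inverse of ``hunger_share`` on the interpolation range."""
    xs = np.log([a[0] for a in params.anchors])
    ys = np.log([a[1] for a in params.anchors])
    ls = np.log(share)
    if not (ys[-1] <= ls <= ys[0]):
        raise HungerConfigError("share outside the interpolation range")
    # ys decreasing: interp on reversed arrays
    x = float(np.interp(ls, ys[::-1], xs[::-1]))
    return float(np.exp(x) * params.requirement)


def population_at_risk(share: float, population_millions: float) -> float:
    if not (0.0 <= share <= 1.0):
        raise HungerConfigError("share must lie in [0, 1]")
    return share * population_millions


def calibrate_hunger_curve(world: WorldConfig) -> HungerCurveParams:
    """Place curve anchors at the built world's 2010 kcal ratios so the
    printed 2010 shares are reproduced exactly.

    Eastern and Central Africa take their printed shares; Northern and
    Southern Africa are fixed at 5 % and 6 % by convention; Western Africa's
    share is solved so the population-weighted Africa aggregate equals 21 %.
    """
    pop = world.macro_anchors["pop_2010"]
    kcal = {r: world.kcal_per_capita(r) for r in (NAF, WAF, EAF, CAF, SAF)}
    shares = dict(SHARE_2010_CONVENTION)
    shares[EAF] = SHARE_2010[EAF]
    shares[CAF] = SHARE_2010[CAF]
    pop_afr = float(pop[[NAF, WAF, EAF, CAF, SAF]].sum())
    known = sum(float(pop[r]) * shares[r] for r in (NAF, EAF, CAF, SAF))
    s_waf = (SHARE_2010[AFR] * pop_afr - known) / float(pop[WAF])
    if not (shares[SAF] < s_waf < shares[EAF]):
        raise HungerConfigError(
            f"solved Western-Africa 2010 share {s_waf:.3f} breaks anchor "
            "monotonicity; kcal anchors and share targets are inconsistent")
    shares[WAF] = s_waf
    req = REQUIREMENT_KCAL
    anchors = sorted(
        [(kcal[r] / req, shares[r]) for r in (NAF, WAF, EAF, CAF, SAF)]
        + [TAIL_ANCHOR]
    )
    return HungerCurveParams(anchors)


def indicators_from_kcal(region_id: str, scenario: str, years: np.ndarray,
                         kcal_path: np.ndarray, population_path: np.ndarray,
                         params: HungerCurveParams) -> HungerIndicators:
    shares = np.array([hunger_share(k, params) for k in kcal_path])
    millions = shares * population_path
    return HungerIndicators(region_id, scenario, np.asarray(years),
                            np.asarray(kcal_path), shares, millions)


def aggregate_indicators(region_id: str, parts: list[HungerIndicators]
                         ) -> HungerIndicators:
    """Aggregate by summing millions at risk and population-weighting kcal —
    never by averaging shares."""
    years = parts[0].years
    pops = np.array([p.millions_at_risk / np.where(p.share_at_risk > 0,
                                                   p.share_at_risk, 1.0)
                     for p in parts])
    pop_total = pops.sum(axis=0)
    millions = np.sum([p.millions_at_risk for p in parts], axis=0)
    kcal = np.sum([p.kcal_pc * pop for p, pop in zip(parts, pops)], axis=0) / pop_total
    return HungerIndicators(region_id, parts[0].scenario, years, kcal,
                            millions / pop_total, millions)


def threshold_report(indicators: dict[str, HungerIndicators], year: int,
                     threshold: float = HUNGER_THRESHOLD) -> dict:
    """Regions whose share at risk is at or below the threshold (inclusive)."""
    meeting = []
    for r, ind in indicators.items():
        i = int(np.searchsorted(ind.years, year))
        if ind.years[i] != year:
            raise HungerConfigError(f"year {year} not in indicators for {r}")
        if ind.share_at_risk[i] <= threshold:
            meeting.append(r)
    return {"year": year, "threshold": threshold, "meeting": sorted(meeting),
            "count": len(meeting), "total": len(indicators)}
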