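"""Perpetual-inventory R&D knowledge stocks and TFP growth.

The knowledge stock follows K_t = (1 - delta) K_{t-1} + sum_l w_l I_eff,t-l
where the lag weights w_l describe the gestation between spending and usable
knowledge, delta is obsolescence decay, and I_eff adds spillover-weighted
foreign investment.  Annual TFP growth is eta times the growth rate of the
stock, and the inverse problem — what additional investment stream achieves
a target 2030 productivity multiplier — is solved by bisection on a single
scale factor applied to a fixed temporal profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

INSTITUTIONS = ("CGIAR", "NARS", "capital")
RND_INSTITUTIONS = ("CGIAR", "NARS")
CATEGORIES = ("R&D", "irrigation_expansion", "water_use_efficiency",
              "soil_management", "infrastructure")


class PimError(ValueError):
    pass


@dataclass
class InvestmentStream:
    """Annual investments, billion 2005 USD, for one region/institution/category."""

    region_id: str
    institution: str
    category: str
    years: np.ndarray
    amounts: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.amounts = np.asarray(self.amounts, dtype=float)
        if self.institution not in INSTITUTIONS:
            raise PimError(f"unknown institution {self.institution!r}")
        if self.category not in CATEGORIES:
            raise PimError(f"unknown category {self.category!r}")
        if self.category == "R&D" and self.institution not in RND_INSTITUTIONS:
            raise PimError("R&D streams must come from CGIAR or NARS")
        if np.any(self.amounts < 0):
            raise PimError(f"negative investment in stream for {self.region_id}")
        if len(self.years) != len(self.amounts):
            raise PimError("years and amounts length mismatch")

    def average(self, start: int, stop: int) -> float:
        """Mean annual amount over [start, stop] inclusive."""
        mask = (self.years >= start) & (self.years <= stop)
        return float(self.amounts[mask].mean())

    def scaled_add(self, other: "InvestmentStream", scale: float) -> "InvestmentStream":
        if not np.array_equal(self.years, other.years):
            raise PimError("cannot add streams on different year grids")
        return InvestmentStream(self.region_id, self.institution, self.category,
                                self.years, self.amounts + scale * other.amounts)


def trapezoid_lags(length: int, peak: int) -> np.ndarray:
    """Gestation-shaped lag weights: linear rise to the peak year then linear
    fall, normalized to sum to one."""
    w = np.zeros(length)
    for l in range(length):
        if l <= peak:
            w[l] = (l + 1) / (peak + 1)
        else:
            w[l] = max(0.0, (length - l) / (length - peak))
    return w / w.sum()


@dataclass
class PimParams:
    """PIM parameterization for one research type / institution."""

    research_type: str = "applied"
    decay: float = 0.10
    lag_weights: np.ndarray = field(default_factory=lambda: trapezoid_lags(10, 5))
    stock_elasticity: float = 0.25
    spillover_in: float = 0.0  # weight on foreign investment entering I_eff

    def __post_init__(self) -> None:
        self.lag_weights = np.asarray(self.lag_weights, dtype=float)
        if not (0.0 < self.decay <= 0.3):
            raise PimError(f"decay must lie in (0, 0.3], got {self.decay}")
        if np.any(self.lag_weights < 0) or abs(self.lag_weights.sum() - 1.0) > 1e-9:
            raise PimError("lag weights must be non-negative and sum to 1")
        if self.stock_elasticity <= 0:
            raise PimError("stock elasticity must be positive")
        if not (0.0 <= self.spillover_in <= 1.0):
            raise PimError("spillover weight must lie in [0, 1]")


# Stylized defaults: CGIAR leans basic (longer gestation, higher elasticity),
# NARS leans applied/developmental (shorter gestation, lower elasticity).
def default_params(institution: str) -> PimParams:
    if institution == "CGIAR":
        return PimParams("basic", 0.10, trapezoid_lags(10, 5), 0.25, 0.2)
    if institution == "NARS":
        return PimParams("applied", 0.10, trapezoid_lags(6, 3), 0.15, 0.0)
    raise PimError(f"no PIM defaults for institution {institution!r}")


@dataclass
class KnowledgeStock:
    region_id: str
    institution: str
    years: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.levels < 0):
            raise PimError("knowledge stock cannot be negative")


def _padded(stream: InvestmentStream, n_pad: int) -> tuple[np.ndarray, np.ndarray]:
    """Prepend ``n_pad`` steady pre-period years at the stream's first level."""
    years = np.concatenate([stream.years[0] - np.arange(n_pad, 0, -1), stream.years])
    amounts = np.concatenate([np.full(n_pad, stream.amounts[0]), stream.amounts])
    return years, amounts


def accumulate_stock(stream: InvestmentStream, params: PimParams,
                     K0: Optional[float] = None,
                     foreign: Sequence[InvestmentStream] = ()) -> KnowledgeStock:
    """Run the perpetual inventory recursion over the stream's years.

    The stream is padded backwards with its first-year level to feed the lag
    window.  ``foreign`` streams enter effective investment with weight
    ``params.spillover_in``.  ``K0`` defaults to the steady state of the
    padded pre-period level (I_eff / delta).
    """
    L = len(params.lag_weights)
    years, own = _padded(stream, L)
    eff = own.copy()
    for f in foreign:
        if not np.array_equal(f.years, stream.years):
            raise PimError("foreign stream year grid mismatch")
        _, fa = _padded(f, L)
        eff += params.spillover_in * fa

    if K0 is None:
        K0 = eff[0] / params.decay
    if K0 < 0:
        raise PimError("initial knowledge stock cannot be negative")

    # K0 is the stock at the year before the stream starts; the padded
    # pre-period feeds only the lag window, never the decay recursion.
    keep = len(stream.years)
    K = np.zeros(keep)
    prev = float(K0)
    for i in range(keep):
        t = L + i  # position on the padded grid
        inflow = 0.0
        for l, w in enumerate(params.lag_weights):
            inflow += w * eff[t - l]
        prev = (1.0 - params.decay) * prev + inflow
        K[i] = prev
    return KnowledgeStock(stream.region_id, stream.institution,
                          stream.years.copy(), K)


def tfp_growth(stock: KnowledgeStock, params: PimParams) -> np.ndarray:
    """Cumulative TFP multiplier path implied by stock growth.

    g_t = eta * (K_t / K_{t-1} - 1); the first year is normalized to 1.
    """
    if np.any(stock.levels <= 0):
        raise PimError("zero knowledge stock with non-zero elasticity")
    ratios = stock.levels[1:] / stock.levels[:-1]
    g = params.stock_elasticity * (ratios - 1.0)
    return np.concatenate([[1.0], np.cumprod(1.0 + g)])


def comp_ramp_profile(years: np.ndarray, start_year: int = 2015,
                      growth: float = 0.25) -> np.ndarray:
    """Unit-scale additional-investment shape: zero before ``start_year``,
    then a geometric ramp (investments diverge from the baseline in 2015
    and accelerate towards 2030)."""
    prof = np.zeros(len(years))
    for i, y in enumerate(years):
        if y > start_year:
            prof[i] = (1.0 + growth) ** (y - start_year - 1)
    s = prof.sum()
    return prof / s if s > 0 else prof


def required_investment(target_mult_final: float, base_stream: InvestmentStream,
                        params: PimParams, profile: Optional[np.ndarray] = None,
                        foreign: Sequence[InvestmentStream] = (),
                        rel_tol: float = 1e-6) -> tuple[InvestmentStream, float]:
    """Invert the PIM: scale an additional stream so the final-year TFP
    multiplier of (base + additional) reaches ``target_mult_final``.

    Returns the additional stream and its scale.  The target is expressed as
    the ratio over the base stream's own TFP multiplier at the final year
    (1.0 means no additional investment).  Bisection brackets are expanded
    geometrically until the sign changes; failure to bracket within 2^20
    raises a nonconvergence error.
    """
    if profile is None:
        profile = comp_ramp_profile(base_stream.years)
    profile = np.asarray(profile, dtype=float)
    unit = InvestmentStream(base_stream.region_id, base_stream.institution,
                            base_stream.category, base_stream.years, profile)

    base_mult = tfp_growth(accumulate_stock(base_stream, params, foreign=foreign),
                           params)[-1]

    def uplift(scale: float) -> float:
        total = base_stream.scaled_add(unit, scale)
        mult = tfp_growth(accumulate_stock(total, params, foreign=foreign),
                          params)[-1]
        return mult / base_mult

    if target_mult_final < 1.0 - rel_tol:
        raise PimError("target productivity below the baseline path is infeasible")
    if uplift(0.0) >= target_mult_final * (1.0 - rel_tol):
        zero = InvestmentStream(base_stream.region_id, base_stream.institution,
                                base_stream.category, base_stream.years,
                                np.zeros(len(profile)))
        return zero, 0.0

    hi = 1.0
    for _ in range(21):
        if uplift(hi) >= target_mult_final:
            break
        hi *= 2.0
    else:
        raise PimError("required_investment: no bracket within 2^20x scaling")

    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        u = uplift(mid)
        if abs(u - target_mult_final) <= rel_tol * target_mult_final:
            lo = hi = mid
            break
        if u < target_mult_final:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    add = InvestmentStream(base_stream.region_id, base_stream.institution,
                           base_stream.category, base_stream.years,
                           scale * profile)
    return add, scale
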