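"""Reduced-form economy-wide income feedback.

Stands in for a full general-equilibrium link: regional real-income
deviations from the baseline trajectory are proportional to the food
value-added share of GDP times the realized agricultural-productivity
deviation, with a single pass-through coefficient kappa calibrated against
the Africa COMP-vs-CC income anchor.  The market model and the income
update are iterated to a fixed point (productivity deviations are weighted
by current equilibrium supply quantities, which respond to incomes through
prices, so the loop is a genuine—mildly contracting—fixed-point problem).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class FeedbackError(RuntimeError):
    pass


@dataclass
class IncomeDeviation:
    """Fractional deviation of per-capita income from the baseline path."""

    region_id: str
    years: np.ndarray
    delta_y: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.delta_y <= -1.0):
            raise FeedbackError(
                f"income deviation at or below -100 % for {self.region_id}")


def income_deviation(tfp_delta: float, va_share: float, kappa: float) -> float:
    """delta_y = kappa * va_share * tfp_delta (linear reduced form)."""
    if not (0.0 <= va_share <= 1.0):
        raise FeedbackError("food value-added share must lie in [0, 1]")
    if kappa < 0:
        raise FeedbackError("pass-through kappa must be non-negative")
    return kappa * va_share * tfp_delta


def productivity_deviations(supply: pd.DataFrame, productivity_ratio: pd.DataFrame
                            ) -> pd.Series:
    """Supply-value-weighted productivity deviation per leaf region.

    ``productivity_ratio`` is scenario productivity over the constant-climate
    baseline (shock x additional-TFP); weights are current supply quantities,
    so the measure responds to the equilibrium the economy actually reaches.
    """
    w = supply.div(supply.sum(axis=1), axis=0)
    return (w * (productivity_ratio - 1.0)).sum(axis=1)


def update_incomes(base_income_ratio: pd.DataFrame, tfp_delta: pd.Series,
                   va_shares: pd.Series, kappa: float) -> pd.DataFrame:
    """Apply the linear reduced form to every region/year.

    ``base_income_ratio``: year x region baseline per-capita income ratios;
    ``tfp_delta``: year x region (as DataFrame) or region Series of
    deviations.  Returns adjusted income ratios.
    """
    if isinstance(tfp_delta, pd.Series):
        adj = 1.0 + kappa * va_shares * tfp_delta
        return base_income_ratio.mul(adj, axis=1)
    adj = 1.0 + kappa * tfp_delta.mul(va_shares, axis=1)
    return base_income_ratio * adj
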