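"""Cashflow assembly and discounting.

Each production year nets three revenue streams (calf sales, cull-cow
salvage, cull-bull salvage) against three costs (heifer replacements for
every culled or dead cow, bull replacements for every culled or dead bull,
and bull maintenance including the exam fee under the tested strategy).
Cow maintenance is identical between strategies and deliberately absent.
Cashflows discount at the cost of capital with the first production year at
exponent 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import BudgetParams, StrategyConfig
from .culling import CullOutcome

__all__ = [
    "AnnualCashflow",
    "NPVResult",
    "cull_revenue",
    "bull_maintenance",
    "replacement_costs",
    "annual_net_cashflow",
    "npv",
]


@dataclass(frozen=True)
class AnnualCashflow:
    """Revenue and cost components ($) for one production year."""

    calf_revenue: float
    cull_cow_revenue: float
    cull_bull_revenue: float
    cow_replacement_cost: float
    bull_replacement_cost: float
    bull_maintenance_cost: float

    @property
    def net(self) -> float:
        return (
            self.calf_revenue
            + self.cull_cow_revenue
            + self.cull_bull_revenue
            - self.cow_replacement_cost
            - self.bull_replacement_cost
            - self.bull_maintenance_cost
        )


@dataclass(frozen=True)
class NPVResult:
    """Discounted value of a cashflow series."""

    npv: float
    per_period_discounted: np.ndarray
    horizon: int
    discount_rate: float


def cull_revenue(count: float, weight: float, price: float) -> float:
    """Salvage revenue: head count x weight x price per lb."""
    if count < 0:
        raise ValueError(f"cull count must be non-negative, got {count!r}")
    return count * weight * price


def bull_maintenance(
    bulls: int, strategy: StrategyConfig, params: BudgetParams
) -> float:
    """Annual bull-battery maintenance, including the exam fee if testing."""
    if bulls < 0:
        raise ValueError("bull count must be non-negative")
    fee = params.bse_fee if strategy.uses_bse else 0.0
    return bulls * (params.bull_maintenance_cost + fee)


def replacement_costs(
    outcome: CullOutcome, params: BudgetParams
) -> tuple[float, float]:
    """(cow, bull) replacement purchases restoring herd sizes.

    Every culled or dead cow is replaced by a bred heifer and every culled
    or dead bull by a purchased bull, booked in the same period as the
    cull/death.
    """
    cow_cost = (
        outcome.total_cow_culls + outcome.cow_deaths
    ) * params.heifer_purchase_price
    bull_cost = (
        outcome.total_bull_culls + outcome.bull_deaths
    ) * params.bull_purchase_price
    return cow_cost, bull_cost


def annual_net_cashflow(
    calf_revenue: float,
    cull_cow_revenue: float,
    cull_bull_revenue: float,
    cow_replacement_cost: float,
    bull_replacement_cost: float,
    bull_maintenance_cost: float,
) -> AnnualCashflow:
    """Assemble one year's cashflow ledger; ``.net`` is revenues less costs."""
    return AnnualCashflow(
        calf_revenue=calf_revenue,
        cull_cow_revenue=cull_cow_revenue,
        cull_bull_revenue=cull_bull_revenue,
        cow_replacement_cost=cow_replacement_cost,
        bull_replacement_cost=bull_replacement_cost,
        bull_maintenance_cost=bull_maintenance_cost,
    )


def npv(cashflows: Sequence[float], discount_rate: float) -> NPVResult:
    """Net present value of annual cashflows at ``discount_rate``.

    The first entry is one period in the future (exponent 1); with a zero
    rate the NPV reduces to the plain sum.
    """
    if discount_rate < 0:
        raise ValueError("discount rate must be non-negative")
    cf = np.asarray(cashflows, dtype=float)
    if cf.ndim != 1 or cf.size == 0:
        raise ValueError("cashflows must be a non-empty 1-D sequence")
    factors = (1.0 + discount_rate) ** -np.arange(1, cf.size + 1)
    discounted = cf * factors
    return NPVResult(
        npv=float(discounted.sum()),
        per_period_discounted=discounted,
        horizon=cf.size,
        discount_rate=discount_rate,
    )
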