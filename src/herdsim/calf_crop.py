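"""Calf crop: weaned counts, ages, weights, price assignment, revenue.

All calves are weaned and sold 225 d after the scheduled start of the
calving season. A calf conceived in cycle ``k`` is, on average, born in the
middle of that cycle, so the cycle-1 cohort averages 225 - 10.5 = 214.5 d at
weaning and each later cohort is exactly 21 d (one estrus cycle) younger.
Weaning weight is birth weight + ADG x age. Each cohort's average weight is
priced on the slide: weight ``w`` falls in the half-open 50-lb class
``(lo, lo + 50]`` and sells at the ``lo``-row price, so heavier cohorts
fetch a lower unit price but more total dollars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np

from .params import BudgetParams, PriceSlide

__all__ = [
    "CalfCohort",
    "weaning_age",
    "weaning_weight",
    "price_for_weight",
    "calf_cohorts",
    "annual_calf_revenue",
    "average_weaning_weight",
    "cycle_weights",
    "cycle_prices",
    "calf_revenue_by_year",
    "average_weaning_weight_by_year",
]

WEANING_DAY = 225.0      # days after calving-season start when calves sell
CYCLE_LENGTH_DAYS = 21.0  # average bovine estrus cycle


@dataclass(frozen=True)
class CalfCohort:
    """Weaned calves conceived in one estrus cycle of one year."""

    cycle: int
    count: float          # fractional: expected conceptions x survival
    age_at_weaning: float  # days
    weight: float          # lb
    unit_price: float      # $/lb

    @property
    def revenue(self) -> float:
        return self.count * self.weight * self.unit_price


def weaning_age(cycle: int) -> float:
    """Average age (days) at weaning for calves conceived in ``cycle``."""
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle!r}")
    return WEANING_DAY - CYCLE_LENGTH_DAYS / 2 - CYCLE_LENGTH_DAYS * (cycle - 1)


def weaning_weight(age: float, birth_weight: float, adg: float) -> float:
    """Weaning weight in lb: birth weight plus ADG x age."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age!r}")
    return birth_weight + adg * age


def price_for_weight(weight: float, slide: PriceSlide) -> float:
    """Unit price for a calf of ``weight`` lb under the half-open class rule.

    Weight ``w`` belongs to class ``(lo, lo + 50]`` and is priced at the
    ``lo`` row: 509 lb falls in (500, 550] and prices at the 500 row, while
    an exact multiple of 50 falls in the lower class (500 lb is in
    (450, 500] and prices at the 450 row). Weights outside the slide clamp
    to its end classes.
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight!r}")
    lo = 50.0 * (math.ceil(weight / 50.0) - 1)
    lo = min(max(lo, slide.min_class), slide.max_class)
    return slide.price_at(lo)


def calf_cohorts(
    year_conceptions: Sequence[float],
    alpha: float,
    delta: float,
    params: BudgetParams,
    slide: PriceSlide,
) -> list[CalfCohort]:
    """Build the weaned-calf cohorts for one year.

    ``alpha`` is the fraction of pregnancies not aborted after diagnosis and
    ``delta`` the fraction of live calves surviving to weaning; the weaned
    count per cycle is ``IC_k * alpha * delta``.
    """
    for name, v in (("alpha", alpha), ("delta", delta)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1], got {v!r}")
    cohorts = []
    for k, ic in enumerate(year_conceptions, start=1):
        age = weaning_age(k)
        w = weaning_weight(age, params.calf_birth_weight, params.calf_adg)
        cohorts.append(
            CalfCohort(
                cycle=k,
                count=float(ic) * alpha * delta,
                age_at_weaning=age,
                weight=w,
                unit_price=price_for_weight(w, slide),
            )
        )
    return cohorts


def annual_calf_revenue(cohorts: Sequence[CalfCohort]) -> float:
    """Total calf sale revenue for one year: sum of count x weight x price."""
    return float(sum(c.revenue for c in cohorts))


def average_weaning_weight(cohorts: Sequence[CalfCohort]) -> float:
    """Calf-count-weighted mean weaning weight across cohorts."""
    total = sum(c.count for c in cohorts)
    if total <= 0:
        raise ValueError("cannot average weaning weight over zero calves")
    return float(sum(c.count * c.weight for c in cohorts) / total)


# ---------------------------------------------------------------------------
# vectorized helpers used by the deterministic grid and the Monte Carlo engine

def cycle_weights(cycles: int, params: BudgetParams) -> np.ndarray:
    """Per-cycle weaning weights (lb), shape (cycles,)."""
    ages = np.array([weaning_age(k) for k in range(1, cycles + 1)])
    return params.calf_birth_weight + params.calf_adg * ages


def cycle_prices(weights: np.ndarray, slide: PriceSlide) -> np.ndarray:
    """Slide prices ($/lb) for an array of cohort weights."""
    return np.array([price_for_weight(float(w), slide) for w in weights])


def calf_revenue_by_year(
    conceptions: np.ndarray,
    survival: float,
    params: BudgetParams,
    slide: PriceSlide,
) -> np.ndarray:
    """Annual calf revenue ($) for a (years x cycles) conception array.

    ``survival`` is the combined product alpha x delta.
    """
    w = cycle_weights(conceptions.shape[1], params)
    p = cycle_prices(w, slide)
    return (conceptions * survival) @ (w * p)


def average_weaning_weight_by_year(
    conceptions: np.ndarray, params: BudgetParams
) -> np.ndarray:
    """Count-weighted mean weaning weight per year (survival cancels)."""
    w = cycle_weights(conceptions.shape[1], params)
    return (conceptions @ w) / conceptions.sum(axis=1)
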