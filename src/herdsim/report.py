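"""Deterministic summary grids: cows bred, weaning weights, calf revenue.

Builds the herd-average grids over season length (rows, 2-6 estrus cycles)
and per-cycle fertility (columns, 66% down to 54%) that summarize the
deterministic layer of the model. Display rounding follows the published
conventions: cows bred round up to whole cows, weights to the nearest
pound, revenue to the nearest thousand dollars.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .params import BudgetParams, PriceSlide, SimulationSettings
from .reproduction import average_cows_bred, simulate_reproduction
from .calf_crop import calf_revenue_by_year, cycle_weights

__all__ = [
    "DEFAULT_FERTILITIES",
    "deterministic_grids",
    "display_grids",
]

#: Column fertilities: the 66% ceiling down to the 54% floor in 1% steps.
DEFAULT_FERTILITIES = tuple(round(0.66 - 0.01 * i, 2) for i in range(13))


def deterministic_grids(
    params: BudgetParams,
    slide: PriceSlide,
    settings: SimulationSettings,
    season_lengths: Sequence[int] = (2, 3, 4, 5, 6),
    fertilities: Sequence[float] = DEFAULT_FERTILITIES,
) -> dict[str, pd.DataFrame]:
    """Unrounded herd averages over the planning horizon.

    Returns ``{"cows_bred", "weaning_weight", "calf_revenue"}`` DataFrames
    indexed by season length with fertility columns. Revenue is in dollars;
    weaning weight is the calf-count-weighted average in lb.
    """
    survival = settings.calf_survival
    idx = pd.Index(list(season_lengths), name="K")
    cols = pd.Index([f"{f:.0%}" for f in fertilities], name="fertility")
    cows = pd.DataFrame(index=idx, columns=cols, dtype=float)
    weights = pd.DataFrame(index=idx, columns=cols, dtype=float)
    revenue = pd.DataFrame(index=idx, columns=cols, dtype=float)
    for K in season_lengths:
        w = cycle_weights(K, params)
        for f, col in zip(fertilities, cols):
            matrix = simulate_reproduction(
                settings.herd_size, K, f, settings.horizon
            )
            cows.loc[K, col] = average_cows_bred(matrix)
            weights.loc[K, col] = (matrix.values @ w).sum() / matrix.values.sum()
            revenue.loc[K, col] = calf_revenue_by_year(
                matrix.values, survival, params, slide
            ).mean()
    return {"cows_bred": cows, "weaning_weight": weights, "calf_revenue": revenue}


def display_grids(grids: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Apply display rounding to :func:`deterministic_grids` output.

    Cows bred round up (a fractional expected cow is a cow bred); weights
    round to the nearest pound; revenue to the nearest thousand dollars.
    """
    out = {}
    out["cows_bred"] = grids["cows_bred"].map(
        lambda x: int(math.ceil(x - 1e-9))
    )
    out["weaning_weight"] = grids["weaning_weight"].map(
        lambda x: int(np.floor(x + 0.5))
    )
    out["calf_revenue"] = grids["calf_revenue"].map(
        lambda x: int(np.floor(x / 1000.0 + 0.5))
    )
    return out
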