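"""Deterministic herd-reproduction recursion.

The number of cows impregnated in cycle ``k`` of a year is an expected-value
recursion, not a random draw:

    IC_k = (CH - sum_{j<k} IC_j) * e_k * f

where ``CH`` is the (constant) cow-herd size, ``f`` the per-cycle conception
probability (bull fertility is the rate-limiting factor), and ``e_k`` the
fraction of the herd eligible to conceive in cycle ``k``. Every cow is
eligible in every cycle of year 1. From year 2 on, a 2.5-cycle postpartum
anestrus makes cows bred late the previous year unavailable early in the
season: for cycle ``k``, cows bred in previous-year cycles ``<= k+1`` are
fully eligible, cows bred in cycle ``k+2`` are half eligible, and cows bred
later are ineligible. Open cows are culled and replaced with bred heifers
calving in the first two cycles, so they re-enter fully eligible.

Counts are fractional by design: the recursion propagates expectations, and
the published herd averages are only reproducible with a deterministic
fractional recursion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConceptionMatrix",
    "lagged_eligibility",
    "eligibility_vector",
    "conceptions_for_year",
    "simulate_reproduction",
    "average_cows_bred",
]


@dataclass(frozen=True)
class ConceptionMatrix:
    """Expected cows impregnated per (year, cycle).

    ``values[t, k]`` is the expected number of cows conceiving in cycle
    ``k+1`` of year ``t+1``; shape is (horizon, season length).
    """

    values: np.ndarray
    herd_size: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("conception matrix must be 2-D and non-empty")
        if (v < 0).any():
            raise ValueError("conception counts must be non-negative")
        if (v.sum(axis=1) > self.herd_size * (1 + 1e-12)).any():
            raise ValueError("annual conceptions exceed the herd size")

    @property
    def horizon(self) -> int:
        return self.values.shape[0]

    @property
    def cycles(self) -> int:
        return self.values.shape[1]

    def annual_totals(self) -> np.ndarray:
        """Total cows impregnated each year, shape (horizon,)."""
        return self.values.sum(axis=1)

    def pregnant_fraction(self) -> np.ndarray:
        return self.annual_totals() / self.herd_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.RangeIndex(1, self.horizon + 1, name="year"),
            columns=[f"cycle_{k}" for k in range(1, self.cycles + 1)],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def lagged_eligibility(
    prev_year: Sequence[float], k: int, herd_size: float
) -> float:
    """Fraction of the herd eligible to conceive in cycle ``k`` (1-based).

    ``prev_year`` holds the previous year's per-cycle conceptions. Cows bred
    in previous cycles ``>= k+2`` are subtracted from the herd, with half of
    cycle ``k+2`` added back (the midpoint of the 2.5-cycle anestrus). When
    ``k+2`` exceeds the season length every cow is eligible.
    """
    prev = np.asarray(prev_year, dtype=float)
    K = prev.shape[0]
    if not 1 <= k <= K:
        raise ValueError(f"cycle index {k} out of range 1..{K}")
    first_blocked = k + 2
    if first_blocked > K:
        return 1.0
    blocked = prev[first_blocked - 1 :].sum()
    base = (herd_size - blocked) / herd_size
    if base >= 1.0:
        return 1.0
    return base + prev[first_blocked - 1] / (2.0 * herd_size)


def eligibility_vector(
    prev_year: Sequence[float], herd_size: float
) -> np.ndarray:
    """Per-cycle eligibility fractions derived from last year's conceptions."""
    K = len(prev_year)
    return np.array(
        [lagged_eligibility(prev_year, k, herd_size) for k in range(1, K + 1)]
    )


def conceptions_for_year(
    herd_size: float,
    cycles: int,
    fertility: float,
    eligibility: Sequence[float] | None = None,
) -> np.ndarray:
    """Apply the per-cycle conception recursion within one year.

    ``eligibility`` defaults to all ones (year-1 behaviour). Returns the
    per-cycle expected conceptions; their sum never exceeds the herd.
    """
    if not 0.0 <= fertility <= 1.0:
        raise ValueError(f"fertility must lie in [0, 1], got {fertility!r}")
    e = np.ones(cycles) if eligibility is None else np.asarray(eligibility, float)
    if e.shape != (cycles,):
        raise ValueError("eligibility vector length must equal the cycle count")
    if ((e < 0) | (e > 1)).any():
        raise ValueError("eligibility entries must lie in [0, 1]")
    out = np.empty(cycles)
    bred = 0.0
    for k in range(cycles):
        out[k] = (herd_size - bred) * e[k] * fertility
        bred += out[k]
    return out


def simulate_reproduction(
    herd_size: int, cycles: int, fertility: float, horizon: int
) -> ConceptionMatrix:
    """Run the reproduction recursion over the full planning horizon.

    Year 1 uses all-ones eligibility; each later year derives eligibility
    from the previous year's conceptions via :func:`lagged_eligibility`.
    For a 2-cycle season the lag never binds and every year is identical.
    """
    if horizon < 1:
        raise ValueError("horizon must be at least one year")
    values = np.empty((horizon, cycles))
    values[0] = conceptions_for_year(herd_size, cycles, fertility)
    for t in range(1, horizon):
        e = eligibility_vector(values[t - 1], herd_size)
        values[t] = conceptions_for_year(herd_size, cycles, fertility, e)
    return ConceptionMatrix(values=values, herd_size=herd_size)


def average_cows_bred(matrix: ConceptionMatrix) -> float:
    """Mean annual total of cows impregnated over the horizon."""
    return float(matrix.annual_totals().mean())
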