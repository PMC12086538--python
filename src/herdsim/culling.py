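"""Stochastic culling and mortality.

Bulls face a sequence of independent binomial culling events each year —
injury/temperament first, then (under the tested strategy only) failing the
soundness exam, then age — where only survivors of one event are eligible
for the next. The sequential structure makes the total a Poisson-binomial
random variable whose mean and variance have simple closed forms
(:func:`expected_bull_culls`). Cows split into a deterministic open-cow cull
(everyone not pregnant at diagnosis) and a binomial nonreproductive cull
drawn from the pregnant pool. Mortality is a separate binomial draw over the
whole herd; dead animals are replaced at purchase price but generate no
salvage revenue.

All draws accept an optional ``size`` so the Monte Carlo engine can draw
whole (iterations x years) panels at once.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .params import StrategyConfig

__all__ = [
    "CullOutcome",
    "RngStreams",
    "draw_binomial",
    "bull_cull_cascade",
    "expected_bull_culls",
    "cow_culls",
    "mortality_draws",
]


@dataclass(frozen=True)
class CullOutcome:
    """Cull and mortality counts for one production period.

    Stochastic counts are integers; ``cows_open`` is fractional because it
    comes from the deterministic conception recursion.
    """

    bulls_injury: int
    bulls_test_fail: int
    bulls_age: int
    cows_open: float
    cows_nonreproductive: int
    cow_deaths: int
    bull_deaths: int

    @property
    def total_bull_culls(self) -> int:
        return self.bulls_injury + self.bulls_test_fail + self.bulls_age

    @property
    def total_cow_culls(self) -> float:
        return self.cows_open + self.cows_nonreproductive


class RngStreams:
    """Named, reproducible substreams of a single master seed.

    ``streams.substream("bse", iteration=3)`` always yields the same
    generator for the same master seed, and distinct labels yield
    statistically independent streams (distinct ``SeedSequence`` spawn
    keys derived from a stable CRC of the labels).
    """

    def __init__(self, seed: int):
        self.seed = int(seed)

    def substream(self, *labels: object, **kw: object) -> np.random.Generator:
        parts = [str(x) for x in labels]
        parts += [f"{k}={v}" for k, v in sorted(kw.items())]
        key = zlib.crc32("/".join(parts).encode())
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,))
        )


def draw_binomial(n, p: float, rng: np.random.Generator, size=None):
    """Binomial draw(s) with validated parameters.

    ``n`` may be a scalar or array of trial counts; with ``size`` given the
    draw broadcasts to that shape.
    """
    if np.any(np.asarray(p) < 0) or np.any(np.asarray(p) > 1):
        raise ValueError(f"probability must lie in [0, 1], got {p!r}")
    if np.any(np.asarray(n) < 0):
        raise ValueError("trial count must be non-negative")
    return rng.binomial(n, p, size=size)


def bull_cull_cascade(
    bulls: int, strategy: StrategyConfig, rng: np.random.Generator, size=None
):
    """Sequential bull culling draws: (injury, test failure, age).

    Injury draws from the whole battery; under the tested strategy the exam
    failure draws from the injury survivors and age from the remainder;
    without testing, the failure count is zero and age draws from the
    injury survivors directly. No bull can be culled twice.
    """
    injury = draw_binomial(bulls, strategy.p_injury_cull, rng, size=size)
    if strategy.uses_bse:
        test_fail = draw_binomial(bulls - injury, strategy.p_test_fail, rng)
    else:
        test_fail = np.zeros_like(injury) if size is not None else 0
    age = draw_binomial(bulls - injury - test_fail, strategy.p_age_cull, rng)
    return injury, test_fail, age


def expected_bull_culls(bulls: int, strategy: StrategyConfig) -> tuple[float, float]:
    """Exact mean and variance of total bull culls per period.

    Because the cascade thins the battery bull by bull, each bull is culled
    with total probability ``P = p_I + (1-p_I)p_T + (1-p_I)(1-p_T)p_A`` and
    the period total is exactly ``Binomial(BH, P)``: mean ``BH*P`` — which
    equals the stage-wise sum ``BH*p_I + BH'*p_T + BH''*p_A`` over expected
    survivors ``BH'``, ``BH''`` — and variance ``BH*P*(1-P)``. (Adding the
    stage variances as if the stage sizes were fixed at their expectations
    would overstate the variance; the stages are coupled through the
    survivor counts.)
    """
    probs = [strategy.p_injury_cull]
    if strategy.uses_bse:
        probs.append(strategy.p_test_fail)
    probs.append(strategy.p_age_cull)
    survive = 1.0
    for p in probs:
        survive *= 1.0 - p
    p_total = 1.0 - survive
    return bulls * p_total, bulls * p_total * (1.0 - p_total)


def cow_culls(
    herd_size: int,
    pregnant: float,
    p_nonreproductive: float,
    rng: np.random.Generator,
    size=None,
):
    """(open culls, nonreproductive culls) for one period.

    Open culls are deterministic — every cow not pregnant at diagnosis is
    sold — and fractional, inheriting the expected-value recursion. The
    nonreproductive cull is a binomial draw over the (rounded) pregnant
    pool only: a cow already sold as open cannot also be culled for udder,
    temperament, or age reasons.
    """
    pregnant_arr = np.asarray(pregnant, dtype=float)
    if np.any(pregnant_arr < 0) or np.any(pregnant_arr > herd_size):
        raise ValueError("pregnant count must lie in [0, herd size]")
    open_culls = herd_size - pregnant_arr
    trials = np.rint(pregnant_arr).astype(int)
    nonrepro = draw_binomial(trials, p_nonreproductive, rng, size=size)
    if np.isscalar(pregnant) and size is None:
        return float(open_culls), int(nonrepro)
    return open_culls, nonrepro


def mortality_draws(
    herd_size: int,
    bulls: int,
    strategy: StrategyConfig,
    rng: np.random.Generator,
    size=None,
):
    """(cow deaths, bull deaths) binomial draws over the full herds.

    Deaths trigger replacement purchases but no salvage revenue, and are
    drawn over the maintained herd sizes (animals are replaced within the
    period, so the at-risk pool stays at capacity).
    """
    cow_deaths = draw_binomial(herd_size, strategy.p_cow_mortality, rng, size=size)
    bull_deaths = draw_binomial(bulls, strategy.p_bull_mortality, rng, size=size)
    return cow_deaths, bull_deaths
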