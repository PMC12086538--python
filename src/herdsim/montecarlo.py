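"""Monte Carlo comparison of the tested and untested bull strategies.

For each scenario pair the deterministic layers (reproduction, calf crop)
are computed once per strategy; the stochastic culling and mortality draws
then generate ``n`` independent 50-year cashflow paths per strategy, each
discounted to an NPV. The decision statistic is
``delta_i = NPV_tested,i - NPV_untested,i`` and the headline estimate is
``p_positive = #{delta_i > 0} / n``. Sweeping the full scenario grid traces
the cumulative-probability curves against the fertility difference, and the
indifference point of a curve is the fertility difference where the curve
crosses 0.5.

Each (scenario, strategy) combination draws from its own named substream of
the master seed, so runs are reproducible and strategies are independent by
default; common random numbers can be enabled to share substreams between
the two strategies of a pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .params import (
    BudgetParams,
    PriceSlide,
    ScenarioPair,
    SimulationSettings,
    StrategyConfig,
    bulls_required,
)
from .reproduction import simulate_reproduction
from .calf_crop import calf_revenue_by_year
from .culling import (
    CullOutcome,
    RngStreams,
    bull_cull_cascade,
    cow_culls,
    mortality_draws,
)
from .economics import annual_net_cashflow, bull_maintenance, cull_revenue, npv

__all__ = [
    "IterationResult",
    "SimulationResult",
    "SweepResult",
    "strategy_npvs",
    "run_iteration",
    "run_simulation",
    "sweep",
    "indifference_point",
]


@dataclass(frozen=True)
class IterationResult:
    """Paired NPVs for one Monte Carlo iteration."""

    iteration: int
    npv_bse: float
    npv_nbse: float

    @property
    def delta(self) -> float:
        return self.npv_bse - self.npv_nbse


@dataclass(frozen=True)
class SimulationResult:
    """All iterations of one scenario pair."""

    pair: ScenarioPair
    npv_bse: np.ndarray
    npv_nbse: np.ndarray
    seed: int

    @property
    def deltas(self) -> np.ndarray:
        return self.npv_bse - self.npv_nbse

    @property
    def n_iterations(self) -> int:
        return self.npv_bse.size

    @property
    def p_positive(self) -> float:
        """Fraction of iterations where testing strictly wins (ties lose)."""
        return float((self.deltas > 0).mean())

    @property
    def mean_delta(self) -> float:
        return float(self.deltas.mean())

    @property
    def std_delta(self) -> float:
        return float(self.deltas.std(ddof=1)) if self.n_iterations > 1 else 0.0

    def iteration_results(self) -> list[IterationResult]:
        return [
            IterationResult(i, float(b), float(nb))
            for i, (b, nb) in enumerate(zip(self.npv_bse, self.npv_nbse))
        ]


@dataclass(frozen=True)
class SweepResult:
    """P(delta NPV > 0) over the whole scenario grid, long format."""

    table: pd.DataFrame  # columns: K, d, ratio_bse, ratio_nbse, p_positive, n, seed
    n_iterations: int
    seed: int

    def curve(self, K: int, pairing: tuple[float, float]) -> pd.DataFrame:
        """The p-vs-d curve for one season length and ratio pairing."""
        t = self.table
        sel = (
            (t["K"] == K)
            & (t["ratio_bse"] == pairing[0])
            & (t["ratio_nbse"] == pairing[1])
        )
        return t.loc[sel].sort_values("d").reset_index(drop=True)

    def indifference_points(self) -> pd.DataFrame:
        """First 0.5 crossing of every curve (fertility-difference units)."""
        rows = []
        for (K, rb, rn), grp in self.table.groupby(
            ["K", "ratio_bse", "ratio_nbse"]
        ):
            grp = grp.sort_values("d")
            point = indifference_point(
                grp["d"].to_numpy(), grp["p_positive"].to_numpy()
            )
            rows.append(
                {"K": K, "ratio_bse": rb, "ratio_nbse": rn, "indifference": point}
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# vectorized engine

def strategy_npvs(
    strategy: StrategyConfig,
    settings: SimulationSettings,
    params: BudgetParams,
    slide: PriceSlide,
    rng: np.random.Generator,
    n_iterations: int,
) -> np.ndarray:
    """NPVs of ``n_iterations`` stochastic cashflow paths for one strategy.

    The reproduction recursion and calf revenue are deterministic and shared
    across iterations; only culling and mortality are drawn.
    """
    CH = settings.herd_size
    T = settings.horizon
    BH = bulls_required(CH, strategy.cow_bull_ratio)
    matrix = simulate_reproduction(
        CH, settings.breeding_season, strategy.fertility, T
    )
    pregnant = matrix.annual_totals()                      # (T,)
    calf_rev = calf_revenue_by_year(
        matrix.values, settings.calf_survival, params, slide
    )                                                      # (T,)

    shape = (n_iterations, T)
    injury, test_fail, age = bull_cull_cascade(BH, strategy, rng, size=shape)
    bull_culls = injury + test_fail + age
    open_culls, nonrepro = cow_culls(
        CH, np.broadcast_to(pregnant, shape), strategy.p_cow_nr_cull, rng
    )
    cow_culls_total = open_culls + nonrepro
    cow_deaths, bull_deaths = mortality_draws(CH, BH, strategy, rng, size=shape)

    net = (
        calf_rev[None, :]
        + cow_culls_total * params.cow_cull_weight * params.cow_cull_price
        + bull_culls * params.bull_cull_weight * params.bull_cull_price
        - (cow_culls_total + cow_deaths) * params.heifer_purchase_price
        - (bull_culls + bull_deaths) * params.bull_purchase_price
        - bull_maintenance(BH, strategy, params)
    )
    factors = (1.0 + settings.discount_rate) ** -np.arange(1, T + 1)
    return net @ factors


# ---------------------------------------------------------------------------
# scalar path (audit trail, one iteration at a time)

def _strategy_npv_scalar(
    strategy: StrategyConfig,
    settings: SimulationSettings,
    params: BudgetParams,
    slide: PriceSlide,
    rng: np.random.Generator,
    audit: list[CullOutcome] | None = None,
):
    CH, T = settings.herd_size, settings.horizon
    BH = bulls_required(CH, strategy.cow_bull_ratio)
    matrix = simulate_reproduction(
        CH, settings.breeding_season, strategy.fertility, T
    )
    calf_rev = calf_revenue_by_year(
        matrix.values, settings.calf_survival, params, slide
    )
    maintenance = bull_maintenance(BH, strategy, params)
    nets = []
    for t in range(T):
        injury, test_fail, age = bull_cull_cascade(BH, strategy, rng)
        pregnant = float(matrix.annual_totals()[t])
        open_c, nonrepro = cow_culls(CH, pregnant, strategy.p_cow_nr_cull, rng)
        cow_d, bull_d = mortality_draws(CH, BH, strategy, rng)
        outcome = CullOutcome(
            bulls_injury=int(injury),
            bulls_test_fail=int(test_fail),
            bulls_age=int(age),
            cows_open=open_c,
            cows_nonreproductive=int(nonrepro),
            cow_deaths=int(cow_d),
            bull_deaths=int(bull_d),
        )
        if audit is not None:
            audit.append(outcome)
        cow_cost = (
            outcome.total_cow_culls + outcome.cow_deaths
        ) * params.heifer_purchase_price
        bull_cost = (
            outcome.total_bull_culls + outcome.bull_deaths
        ) * params.bull_purchase_price
        cf = annual_net_cashflow(
            calf_revenue=float(calf_rev[t]),
            cull_cow_revenue=cull_revenue(
                outcome.total_cow_culls,
                params.cow_cull_weight,
                params.cow_cull_price,
            ),
            cull_bull_revenue=cull_revenue(
                outcome.total_bull_culls,
                params.bull_cull_weight,
                params.bull_cull_price,
            ),
            cow_replacement_cost=cow_cost,
            bull_replacement_cost=bull_cost,
            bull_maintenance_cost=maintenance,
        )
        nets.append(cf.net)
    return npv(nets, settings.discount_rate).npv


def run_iteration(
    pair: ScenarioPair,
    settings: SimulationSettings,
    params: BudgetParams,
    slide: PriceSlide,
    streams: RngStreams,
    iteration: int = 0,
    common_random_numbers: bool = False,
    audit: dict[str, list[CullOutcome]] | None = None,
) -> IterationResult:
    """One paired iteration through the scalar cashflow path.

    Each strategy draws from its own substream unless
    ``common_random_numbers`` shares one substream label between them.
    """
    label_bse = ("bse", pair.breeding_season, pair.fertility_diff, pair.pairing)
    label_nbse = (
        ("bse",) if common_random_numbers else ("nbse",)
    ) + (pair.breeding_season, pair.fertility_diff, pair.pairing)
    audit_bse = audit.setdefault("bse", []) if audit is not None else None
    audit_nbse = audit.setdefault("nbse", []) if audit is not None else None
    settings = replace(settings, breeding_season=pair.breeding_season)
    npv_bse = _strategy_npv_scalar(
        pair.bse, settings, params, slide,
        streams.substream(*label_bse, iteration=iteration), audit_bse,
    )
    npv_nbse = _strategy_npv_scalar(
        pair.nbse, settings, params, slide,
        streams.substream(*label_nbse, iteration=iteration), audit_nbse,
    )
    return IterationResult(iteration, npv_bse, npv_nbse)


def run_simulation(
    pair: ScenarioPair,
    settings: SimulationSettings,
    params: BudgetParams,
    slide: PriceSlide,
    n_iterations: int | None = None,
    seed: int | None = None,
    common_random_numbers: bool = False,
) -> SimulationResult:
    """All Monte Carlo iterations for one scenario pair (vectorized)."""
    n = n_iterations if n_iterations is not None else settings.iterations
    if n < 1:
        raise ValueError("need at least one iteration")
    master = seed if seed is not None else settings.seed
    settings = replace(settings, breeding_season=pair.breeding_season)
    streams = RngStreams(master)
    label = (pair.breeding_season, pair.fertility_diff, pair.pairing)
    rng_bse = streams.substream("bse", *label)
    rng_nbse = (
        streams.substream("bse", *label)
        if common_random_numbers
        else streams.substream("nbse", *label)
    )
    npv_bse = strategy_npvs(pair.bse, settings, params, slide, rng_bse, n)
    npv_nbse = strategy_npvs(pair.nbse, settings, params, slide, rng_nbse, n)
    return SimulationResult(pair=pair, npv_bse=npv_bse, npv_nbse=npv_nbse, seed=master)


def sweep(
    grid: Sequence[ScenarioPair],
    settings: SimulationSettings,
    params: BudgetParams,
    slide: PriceSlide,
    n_iterations: int | None = None,
    seed: int | None = None,
    common_random_numbers: bool = False,
) -> SweepResult:
    """P(delta NPV > 0) for every scenario pair in the grid."""
    n = n_iterations if n_iterations is not None else settings.iterations
    master = seed if seed is not None else settings.seed
    rows = []
    for pair in grid:
        result = run_simulation(
            pair, settings, params, slide, n, master, common_random_numbers
        )
        rows.append(
            {
                "K": pair.breeding_season,
                "d": pair.fertility_diff,
                "ratio_bse": pair.bse.cow_bull_ratio,
                "ratio_nbse": pair.nbse.cow_bull_ratio,
                "p_positive": result.p_positive,
                "mean_delta": result.mean_delta,
                "std_delta": result.std_delta,
                "n": n,
                "seed": master,
            }
        )
    return SweepResult(table=pd.DataFrame(rows), n_iterations=n, seed=master)


def indifference_point(
    diffs: Sequence[float], p_positive: Sequence[float]
) -> float | str:
    """Fertility difference where P(delta NPV > 0) first crosses 0.5.

    Linear interpolation between grid points; returns ``"below grid"`` if
    the curve starts above 0.5 and ``"above grid"`` if it never reaches it.
    A non-monotone curve triggers a warning and returns the first crossing.
    """
    d = np.asarray(diffs, dtype=float)
    p = np.asarray(p_positive, dtype=float)
    if d.shape != p.shape or d.size == 0:
        raise ValueError("diffs and p_positive must be equal-length, non-empty")
    if np.any(np.diff(d) <= 0):
        raise ValueError("diffs must be strictly increasing")
    if p[0] > 0.5:
        return "below grid"
    crossings = np.nonzero((p[:-1] < 0.5) & (p[1:] >= 0.5))[0]
    exact = np.nonzero(p == 0.5)[0]
    if exact.size and (not crossings.size or exact[0] <= crossings[0]):
        first = float(d[exact[0]])
    elif crossings.size:
        i = crossings[0]
        frac = (0.5 - p[i]) / (p[i + 1] - p[i])
        first = float(d[i] + frac * (d[i + 1] - d[i]))
    else:
        return "above grid"
    if np.any(np.diff(p) < 0) and (crossings.size + exact.size) > 1:
        warnings.warn(
            "p_positive curve is non-monotone with multiple 0.5 crossings; "
            "returning the first",
            stacklevel=2,
        )
    return first
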