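"""Model parameters, validation, configuration I/O, and the scenario grid.

Everything the simulator needs is a printed budget or management parameter:
there are no external datasets. Parameters are grouped into four frozen
dataclasses — :class:`BudgetParams` (prices, weights, lifespans),
:class:`PriceSlide` (the weight-class price schedule for weaned calves),
:class:`StrategyConfig` (one bull-management strategy: fertility, cow:bull
ratio, culling/mortality probabilities), and :class:`SimulationSettings`
(herd size, horizon, discount rate, breeding-season length, iteration
count, seed). A YAML config file with sections ``budget``, ``prices``,
``bse``, ``nbse`` and ``simulation`` can override any default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "BudgetParams",
    "PriceSlide",
    "StrategyConfig",
    "SimulationSettings",
    "ScenarioPair",
    "DEFAULT_PRICE_SLIDE",
    "load_config",
    "dump_config",
    "bulls_required",
    "scenario_grid",
]


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


def _require_probability(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class BudgetParams:
    """Budget parameters for bulls, cows, and calves.

    Units: dollars, pounds, years, lb/day. Defaults are 2023-vintage
    southeastern-US values (sale-barn averages and a bull cost calculator).
    """

    bull_maintenance_cost: float = 542.30  # $/bull/yr, feed + yardage + vet
    bse_fee: float = 100.0                 # $/bull/yr, veterinary exam fee
    bull_purchase_price: float = 7250.0    # $ per replacement bull
    bull_cull_weight: float = 2000.0       # lb, salvage weight
    bull_cull_price: float = 0.85          # $/lb slaughter bulls
    bull_lifespan: float = 4.0             # yr average working life
    heifer_purchase_price: float = 1116.0  # $ per bred replacement heifer
    cow_cull_weight: float = 1000.0        # lb
    cow_cull_price: float = 0.86           # $/lb slaughter cows
    cow_lifespan: float = 10.0             # yr average working life
    calf_birth_weight: float = 80.0        # lb
    calf_adg: float = 2.0                  # lb/day average daily gain

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "bse_fee":  # zero fee expresses a free exam
                if self.bse_fee < 0:
                    raise ValueError("bse_fee must be non-negative")
                continue
            _require_positive(f.name, getattr(self, f.name))
        if self.bull_lifespan < 1 or self.cow_lifespan < 1:
            raise ValueError("lifespans must be at least 1 year")


@dataclass(frozen=True)
class PriceSlide:
    """Price per pound by 50-lb calf weight class, decreasing in weight.

    ``classes`` is an ordered tuple of ``(class_weight_lb, price_per_lb)``
    pairs. Class weights must increase in strict 50-lb steps; a weight ``w``
    belongs to the half-open class ``(class_weight, class_weight + 50]``
    (see :func:`herdsim.calf_crop.price_for_weight`).
    """

    classes: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("price slide must have at least one class")
        weights = [w for w, _ in self.classes]
        for prev, cur in zip(weights, weights[1:]):
            if cur - prev != 50:
                raise ValueError(
                    f"class weights must increase in 50-lb steps, got {prev} -> {cur}"
                )
        for w, p in self.classes:
            _require_positive(f"price for class {w}", p)

    @property
    def min_class(self) -> float:
        return self.classes[0][0]

    @property
    def max_class(self) -> float:
        return self.classes[-1][0]

    def price_at(self, class_weight: float) -> float:
        """Price of the row whose class weight equals ``class_weight``."""
        for w, p in self.classes:
            if w == class_weight:
                return p
        raise KeyError(f"no {class_weight}-lb row in price slide")


#: 2023 Mississippi steer/heifer price slide, $/lb by weight class.
DEFAULT_PRICE_SLIDE = PriceSlide(
    (
        (250, 2.40),
        (300, 2.41),
        (350, 2.37),
        (400, 2.30),
        (450, 2.23),
        (500, 2.15),
        (550, 2.09),
        (600, 2.01),
        (650, 1.94),
        (700, 1.84),
    )
)


@dataclass(frozen=True)
class StrategyConfig:
    """One bull-management strategy.

    ``uses_bse`` distinguishes the strategy that pays a veterinarian to
    screen every bull annually (test failures are culled) from the one that
    does not. Injury/temperament culling risk defaults higher under testing
    (1 in 10 vs 1 in 20) because gathering and processing bulls is itself a
    risk event. Age culls draw with probability 1/lifespan; nonreproductive
    cow culls likewise. ``p_test_fail`` is ignored when ``uses_bse`` is
    False.
    """

    uses_bse: bool
    fertility: float = 0.66          # per-cycle conception probability
    cow_bull_ratio: float = 25.0     # cows per bull
    p_injury_cull: float | None = None  # default depends on uses_bse
    p_test_fail: float = 0.20
    p_age_cull: float = 0.25         # 1 / bull working lifespan
    p_cow_nr_cull: float = 0.10      # 1 / cow working lifespan
    p_cow_mortality: float = 0.01
    p_bull_mortality: float = 0.01

    def __post_init__(self) -> None:
        if self.p_injury_cull is None:
            object.__setattr__(
                self, "p_injury_cull", 0.10 if self.uses_bse else 0.05
            )
        if not 0.0 < self.fertility <= 1.0:
            raise ValueError(f"fertility must lie in (0, 1], got {self.fertility!r}")
        _require_positive("cow_bull_ratio", self.cow_bull_ratio)
        for name in (
            "p_injury_cull",
            "p_test_fail",
            "p_age_cull",
            "p_cow_nr_cull",
            "p_cow_mortality",
            "p_bull_mortality",
        ):
            _require_probability(name, getattr(self, name))

    @classmethod
    def bse(cls, **overrides) -> "StrategyConfig":
        return cls(uses_bse=True, **overrides)

    @classmethod
    def nbse(cls, **overrides) -> "StrategyConfig":
        return cls(uses_bse=False, **overrides)


@dataclass(frozen=True)
class SimulationSettings:
    """Herd-level and numerical settings shared by both strategies."""

    herd_size: int = 1000        # CH, mature cows, held constant
    horizon: int = 50            # T, production years in the planning horizon
    discount_rate: float = 0.20  # i, total cost of capital
    breeding_season: int = 3     # K, estrus cycles (21 d each) bulls are out
    abortion_rate: float = 0.01  # fraction of pregnancies lost post-diagnosis
    calf_death_loss: float = 0.01  # fraction of live calves lost pre-weaning
    iterations: int = 500        # Monte Carlo iterations per scenario
    seed: int = 20250304

    def __post_init__(self) -> None:
        if self.herd_size < 1 or self.horizon < 1 or self.breeding_season < 1:
            raise ValueError("herd_size, horizon and breeding_season must be >= 1")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be non-negative")
        for name in ("abortion_rate", "calf_death_loss"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {v!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def calf_survival(self) -> float:
        """Combined pregnancy-to-weaning survival, alpha * delta."""
        return (1.0 - self.abortion_rate) * (1.0 - self.calf_death_loss)


@dataclass(frozen=True)
class ScenarioPair:
    """A paired comparison: one tested and one untested strategy."""

    breeding_season: int
    fertility_diff: float
    bse: StrategyConfig
    nbse: StrategyConfig

    @property
    def pairing(self) -> tuple[float, float]:
        """(BSE cow:bull ratio, NBSE cow:bull ratio)."""
        return (self.bse.cow_bull_ratio, self.nbse.cow_bull_ratio)


def bulls_required(herd_size: int, ratio: float) -> int:
    """Number of bulls in the battery: herd size / cow:bull ratio.

    Rounded to the nearest whole bull (1000 cows at 33:1 run 30 bulls,
    matching the "3 bulls per 100 cows" convention).
    """
    if ratio <= 0:
        raise ValueError(f"cow:bull ratio must be positive, got {ratio!r}")
    if herd_size < ratio:
        raise ValueError("herd must have at least one bull's worth of cows")
    return int(math.floor(herd_size / ratio + 0.5))


# ---------------------------------------------------------------------------
# configuration file I/O

_SECTIONS = ("budget", "prices", "bse", "nbse", "simulation")


def _strategy_from_mapping(mapping: dict, uses_bse: bool) -> StrategyConfig:
    mapping = dict(mapping)
    mapping.pop("uses_bse", None)
    return StrategyConfig(uses_bse=uses_bse, **mapping)


def load_config(
    path: str | Path,
) -> tuple[BudgetParams, PriceSlide, tuple[StrategyConfig, StrategyConfig], SimulationSettings]:
    """Read a YAML config; omitted fields fall back to the defaults.

    Returns ``(budget, slide, (bse, nbse), settings)``. Raises
    ``FileNotFoundError`` for a missing file and ``ValueError`` for any
    parameter outside its valid range.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    budget = BudgetParams(**(raw.get("budget") or {}))
    prices = raw.get("prices")
    if prices is None:
        slide = DEFAULT_PRICE_SLIDE
    else:
        slide = PriceSlide(tuple((float(w), float(p)) for w, p in prices))
    bse = _strategy_from_mapping(raw.get("bse") or {}, uses_bse=True)
    nbse = _strategy_from_mapping(raw.get("nbse") or {}, uses_bse=False)
    settings = SimulationSettings(**(raw.get("simulation") or {}))
    return budget, slide, (bse, nbse), settings


def dump_config(
    path: str | Path,
    budget: BudgetParams,
    slide: PriceSlide,
    strategies: tuple[StrategyConfig, StrategyConfig],
    settings: SimulationSettings,
) -> None:
    """Write a config file that :func:`load_config` reproduces exactly."""
    bse, nbse = strategies

    def strat(s: StrategyConfig) -> dict:
        d = {f.name: getattr(s, f.name) for f in fields(s)}
        d.pop("uses_bse")
        return d

    doc = {
        "budget": {f.name: getattr(budget, f.name) for f in fields(budget)},
        "prices": [[w, p] for w, p in slide.classes],
        "bse": strat(bse),
        "nbse": strat(nbse),
        "simulation": {f.name: getattr(settings, f.name) for f in fields(settings)},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# scenario grid

FERTILITY_CEILING = 0.66  #: biological-maximum per-cycle conception rate
SEASON_LENGTHS = (2, 3, 4, 5, 6)  #: breeding-season lengths, estrus cycles
FERTILITY_DIFFS = tuple(round(0.01 * i, 2) for i in range(13))  #: 0.00 .. 0.12
RATIO_PAIRINGS = ((25.0, 25.0), (33.0, 25.0))  #: (BSE, NBSE) cow:bull ratios


def scenario_grid(
    settings: SimulationSettings | None = None,
    *,
    season_lengths: Sequence[int] = SEASON_LENGTHS,
    fertility_diffs: Sequence[float] = FERTILITY_DIFFS,
    pairings: Sequence[tuple[float, float]] = RATIO_PAIRINGS,
    bse_template: StrategyConfig | None = None,
    nbse_template: StrategyConfig | None = None,
) -> list[ScenarioPair]:
    """Full factorial of season length x fertility difference x ratio pairing.

    The tested strategy holds fertility at the 66% ceiling; the untested
    strategy's fertility is the ceiling minus the difference ``d``, so every
    pair satisfies ``f_nbse <= f_bse``. The default grid is
    5 season lengths x 13 differences x 2 pairings = 130 pairs.
    """
    del settings  # grid dimensions are management choices, not settings
    bse_template = bse_template or StrategyConfig.bse(fertility=FERTILITY_CEILING)
    nbse_template = nbse_template or StrategyConfig.nbse(fertility=FERTILITY_CEILING)
    pairs = []
    for K in season_lengths:
        for d in fertility_diffs:
            for ratio_bse, ratio_nbse in pairings:
                bse = replace(
                    bse_template,
                    fertility=FERTILITY_CEILING,
                    cow_bull_ratio=ratio_bse,
                )
                nbse = replace(
                    nbse_template,
                    fertility=round(FERTILITY_CEILING - d, 10),
                    cow_bull_ratio=ratio_nbse,
                )
                pairs.append(
                    ScenarioPair(
                        breeding_season=int(K),
                        fertility_diff=float(d),
                        bse=bse,
                        nbse=nbse,
                    )
                )
    return pairs
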