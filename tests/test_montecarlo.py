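"""Paired simulation, probability curves, and indifference points."""

import numpy as np
import pytest

from herdsim import (
    RngStreams,
    ScenarioPair,
    SimulationSettings,
    StrategyConfig,
    indifference_point,
    run_iteration,
    run_simulation,
    scenario_grid,
    sweep,
)
from herdsim.calf_crop import calf_revenue_by_year
from herdsim.economics import npv
from herdsim.reproduction import simulate_reproduction


def make_pair(K=2, d=0.12, ratios=(25.0, 25.0), **strategy_kw):
    return ScenarioPair(
        breeding_season=K,
        fertility_diff=d,
        bse=StrategyConfig.bse(
            fertility=0.66, cow_bull_ratio=ratios[0], **strategy_kw
        ),
        nbse=StrategyConfig.nbse(
            fertility=0.66 - d, cow_bull_ratio=ratios[1], **strategy_kw
        ),
    )


@pytest.fixture
def fast_settings():
    return SimulationSettings(iterations=200, seed=42)


class TestDeterminism:
    def test_same_seed_identical_results(self, budget, slide, fast_settings):
        pair = make_pair()
        a = run_simulation(pair, fast_settings, budget, slide, 100, seed=9)
        b = run_simulation(pair, fast_settings, budget, slide, 100, seed=9)
        assert (a.npv_bse == b.npv_bse).all()
        assert (a.npv_nbse == b.npv_nbse).all()

    def test_run_iteration_reproducible(self, budget, slide, fast_settings):
        pair = make_pair(K=3, d=0.05)
        r1 = run_iteration(pair, fast_settings, budget, slide, RngStreams(5), 2)
        r2 = run_iteration(pair, fast_settings, budget, slide, RngStreams(5), 2)
        assert r1 == r2
        assert r1.delta == r1.npv_bse - r1.npv_nbse


class TestSharedStreams:
    def test_identical_strategies_with_common_numbers_tie_exactly(
        self, slide, fast_settings
    ):
        from herdsim import BudgetParams

        free_exam = BudgetParams(bse_fee=0)
        strat = StrategyConfig.bse(p_test_fail=0.0, p_injury_cull=0.05)
        pair = ScenarioPair(
            breeding_season=3, fertility_diff=0.0, bse=strat, nbse=strat
        )
        result = run_simulation(
            pair, fast_settings, free_exam, slide, 50, seed=3,
            common_random_numbers=True,
        )
        assert np.all(result.deltas == 0.0)
        assert result.p_positive == 0.0  # exact ties count as not-positive


class TestAllDeterministicScenario:
    def test_delta_matches_closed_form(self, budget, slide):
        """With every culling probability zero the paired delta is exact.

        Oracle: compose the deterministic layers directly — calf revenue
        difference plus the open-cow salvage-minus-replacement difference,
        less the exam-fee annuity — and discount.
        """
        settings = SimulationSettings(seed=1)
        kw = dict(
            p_injury_cull=0.0,
            p_test_fail=0.0,
            p_age_cull=0.0,
            p_cow_nr_cull=0.0,
            p_cow_mortality=0.0,
            p_bull_mortality=0.0,
        )
        pair = make_pair(K=2, d=0.12, **kw)
        result = run_simulation(pair, settings, budget, slide, 5, seed=1)
        assert result.p_positive in (0.0, 1.0)

        T = settings.horizon
        per_year = np.zeros(T)
        for strat, sign in ((pair.bse, +1), (pair.nbse, -1)):
            m = simulate_reproduction(1000, 2, strat.fertility, T)
            calf = calf_revenue_by_year(
                m.values, settings.calf_survival, budget, slide
            )
            open_cows = 1000 - m.annual_totals()
            net = (
                calf
                + open_cows * 1000 * 0.86
                - open_cows * 1116
                - 40 * (542.30 + (100 if strat.uses_bse else 0))
            )
            per_year += sign * net
        expected = npv(per_year, settings.discount_rate).npv
        assert result.deltas == pytest.approx(expected)


class TestNullScenario:
    def test_identical_strategies_split_the_coin(self, slide):
        """Equal costs and fertility with independent draws => p near 1/2."""
        from herdsim import BudgetParams

        free_exam = BudgetParams(bse_fee=0)
        strat_b = StrategyConfig.bse(p_test_fail=0.0, p_injury_cull=0.05)
        strat_n = StrategyConfig.nbse()
        pair = ScenarioPair(
            breeding_season=3, fertility_diff=0.0, bse=strat_b, nbse=strat_n
        )
        settings = SimulationSettings(seed=2)
        n = 2000
        result = run_simulation(pair, settings, free_exam, slide, n, seed=2)
        se = np.sqrt(0.25 / n)
        assert abs(result.p_positive - 0.5) <= 3 * se


class TestSweep:
    def test_small_sweep_layout(self, budget, slide, fast_settings):
        grid = scenario_grid(
            season_lengths=(2, 4),
            fertility_diffs=(0.0, 0.06, 0.12),
        )
        result = sweep(grid, fast_settings, budget, slide, 50, seed=4)
        assert len(result.table) == 2 * 3 * 2
        assert result.table["p_positive"].between(0, 1).all()
        assert (result.table["n"] == 50).all()
        curve = result.curve(2, (25.0, 25.0))
        assert list(curve["d"]) == [0.0, 0.06, 0.12]

    def test_dominant_and_dominated_ends(self, budget, slide, fast_settings):
        grid = scenario_grid(
            season_lengths=(2,), fertility_diffs=(0.0, 0.12),
            pairings=((25.0, 25.0),),
        )
        result = sweep(grid, fast_settings, budget, slide, 200, seed=5)
        by_d = result.table.set_index("d")["p_positive"]
        # equal fertility: testing is strictly costlier, so it rarely wins
        assert by_d[0.0] < 0.5
        # a 12% fertility gap dwarfs the stochastic cost spread
        assert by_d[0.12] > 0.95


class TestIndifferencePoint:
    def test_exact_grid_hit(self):
        assert indifference_point([0.0, 0.01, 0.02], [0.2, 0.5, 0.9]) == 0.01

    def test_midpoint_interpolation(self):
        assert indifference_point([0.0, 0.01], [0.4, 0.6]) == pytest.approx(0.005)

    def test_boundary_contracts(self):
        assert indifference_point([0.0, 0.01], [0.6, 0.9]) == "below grid"
        assert indifference_point([0.0, 0.01], [0.1, 0.4]) == "above grid"

    def test_multiple_crossings_warn_and_return_first(self):
        with pytest.warns(UserWarning):
            point = indifference_point(
                [0.0, 0.01, 0.02, 0.03], [0.4, 0.6, 0.4, 0.8]
            )
        assert point == pytest.approx(0.005)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            indifference_point([0.0, 0.0], [0.1, 0.9])
        with pytest.raises(ValueError):
            indifference_point([], [])
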