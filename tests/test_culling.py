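"""Binomial culling cascades, their closed-form moments, and substreams."""

import numpy as np
import pytest

from herdsim import (
    RngStreams,
    StrategyConfig,
    bull_cull_cascade,
    cow_culls,
    draw_binomial,
    expected_bull_culls,
    mortality_draws,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


class TestDrawBinomial:
    def test_degenerate_probabilities(self, rng):
        assert draw_binomial(17, 0.0, rng) == 0
        assert draw_binomial(17, 1.0, rng) == 17

    def test_invalid_probability(self, rng):
        with pytest.raises(ValueError):
            draw_binomial(10, 1.5, rng)
        with pytest.raises(ValueError):
            draw_binomial(-1, 0.5, rng)

    def test_moments(self, rng):
        draws = draw_binomial(40, 0.25, rng, size=100_000)
        assert draws.mean() == pytest.approx(10.0, abs=0.1)
        assert draws.var() == pytest.approx(7.5, rel=0.05)


class TestCascade:
    def test_empty_battery(self, rng):
        assert bull_cull_cascade(0, StrategyConfig.bse(), rng) == (0, 0, 0)

    def test_totals_never_exceed_battery(self, rng):
        inj, test, age = bull_cull_cascade(
            10, StrategyConfig.bse(), rng, size=5000
        )
        assert ((inj + test + age) <= 10).all()
        assert (inj >= 0).all() and (test >= 0).all() and (age >= 0).all()

    def test_untested_strategy_has_no_test_failures(self, rng):
        _, test, _ = bull_cull_cascade(40, StrategyConfig.nbse(), rng, size=100)
        assert not np.any(test)

    def test_sample_moments_match_closed_form(self, rng):
        for strat in (StrategyConfig.bse(), StrategyConfig.nbse()):
            mu, var = expected_bull_culls(40, strat)
            inj, test, age = bull_cull_cascade(40, strat, rng, size=100_000)
            totals = inj + test + age
            assert totals.mean() == pytest.approx(mu, rel=0.01)
            assert totals.var() == pytest.approx(var, rel=0.01)

    def test_distribution_matches_enumeration(self, rng):
        """Empirical cascade totals match the brute-force Poisson-binomial.

        The oracle enumerates every (injury, test, age) path for a 10-bull
        battery with exact binomial pmfs and accumulates the distribution of
        the total; the simulated distribution must be within total-variation
        distance 0.01.
        """
        from scipy.stats import binom

        strat = StrategyConfig.bse()
        BH = 10
        pmf = np.zeros(BH + 1)
        for i in range(BH + 1):
            pi = binom.pmf(i, BH, strat.p_injury_cull)
            for t in range(BH - i + 1):
                pt = binom.pmf(t, BH - i, strat.p_test_fail)
                for a in range(BH - i - t + 1):
                    pa = binom.pmf(a, BH - i - t, strat.p_age_cull)
                    pmf[i + t + a] += pi * pt * pa
        inj, test, age = bull_cull_cascade(BH, strat, rng, size=100_000)
        empirical = np.bincount(inj + test + age, minlength=BH + 1) / 100_000
        tv = 0.5 * np.abs(empirical - pmf).sum()
        assert tv < 0.01


class TestExpectedCulls:
    def test_tested_battery_closed_form(self):
        mu, var = expected_bull_culls(40, StrategyConfig.bse())
        # stage-wise mean: 40*0.10 + 36*0.20 + 28.8*0.25
        assert mu == pytest.approx(18.4)
        # per-bull cull probability 0.46 => Binomial(40, 0.46) variance
        assert var == pytest.approx(40 * 0.46 * 0.54)

    def test_untested_battery_closed_form(self):
        mu, var = expected_bull_culls(40, StrategyConfig.nbse())
        # 40*0.05 + 38*0.25
        assert mu == pytest.approx(11.5)
        assert var == pytest.approx(40 * 0.2875 * (1 - 0.2875))

    def test_zero_probabilities(self):
        strat = StrategyConfig.bse(
            p_injury_cull=0.0, p_test_fail=0.0, p_age_cull=0.0
        )
        assert expected_bull_culls(25, strat) == (0.0, 0.0)

    def test_testing_culls_more_bulls(self):
        for BH in (1, 10, 40):
            mu_bse, _ = expected_bull_culls(BH, StrategyConfig.bse())
            mu_nbse, _ = expected_bull_culls(BH, StrategyConfig.nbse())
            assert mu_bse > mu_nbse


class TestCowCulls:
    def test_open_cull_is_deterministic(self, rng):
        open_c, nonrepro = cow_culls(1000, 884.4, 0.1, rng)
        assert open_c == pytest.approx(115.6)
        assert 0 <= nonrepro <= 884

    def test_fully_pregnant_herd(self, rng):
        open_c, _ = cow_culls(1000, 1000.0, 0.1, rng)
        assert open_c == 0.0

    def test_zero_nonreproductive_probability(self, rng):
        _, nonrepro = cow_culls(1000, 900.0, 0.0, rng)
        assert nonrepro == 0

    def test_nonreproductive_mean(self, rng):
        _, nonrepro = cow_culls(
            1000, np.full(50_000, 884.4), 0.1, rng
        )
        assert nonrepro.mean() == pytest.approx(88.4, rel=0.02)

    def test_rejects_impossible_pregnancy(self, rng):
        with pytest.raises(ValueError):
            cow_culls(1000, 1500.0, 0.1, rng)


class TestMortality:
    def test_zero_rates(self, rng):
        strat = StrategyConfig.bse(p_cow_mortality=0.0, p_bull_mortality=0.0)
        assert mortality_draws(1000, 40, strat, rng) == (0, 0)

    def test_means_and_bounds(self, rng):
        strat = StrategyConfig.bse()
        cows, bulls = mortality_draws(1000, 40, strat, rng, size=50_000)
        assert cows.mean() == pytest.approx(10.0, rel=0.05)
        assert bulls.mean() == pytest.approx(0.4, rel=0.05)
        assert cows.max() <= 1000 and bulls.max() <= 40


class TestRngStreams:
    def test_same_seed_same_draws(self):
        a = RngStreams(7).substream("bse", iteration=3).integers(0, 1000, 10)
        b = RngStreams(7).substream("bse", iteration=3).integers(0, 1000, 10)
        assert (a == b).all()

    def test_distinct_labels_differ(self):
        s = RngStreams(7)
        a = s.substream("bse", iteration=3).integers(0, 1000, 10)
        b = s.substream("nbse", iteration=3).integers(0, 1000, 10)
        assert (a != b).any()

    def test_cascade_reproducible(self):
        strat = StrategyConfig.bse()
        draws1 = bull_cull_cascade(
            40, strat, RngStreams(11).substream("x"), size=100
        )
        draws2 = bull_cull_cascade(
            40, strat, RngStreams(11).substream("x"), size=100
        )
        for a, b in zip(draws1, draws2):
            assert (a == b).all()
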