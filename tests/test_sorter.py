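"""Scenario model, Monte-Carlo sorter, and throughput/purity metrics."""

from itertools import product

import numpy as np
import pytest

import ramansort as rs

GRID_RATES = (1.0, 10.0, 50.0, 100.0, 200.0)
GRID_TAUS = (0.5e-3, 1.5e-3, 3e-3)
GRID_RS = (0.1, 0.6, 0.9)


class TestIntervalProb:
    def test_zero_window(self):
        assert rs.interval_prob(100.0, 0.0) == 0.0

    def test_half_life(self):
        assert rs.interval_prob(np.log(2) / 1e-3, 1e-3) == pytest.approx(0.5)

    def test_operating_point(self):
        assert rs.interval_prob(50.2, 1.5e-3) == pytest.approx(
            1 - np.exp(-0.0753), rel=1e-12
        )

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            rs.interval_prob(-1.0, 1e-3)


def triple_times(tau, gap_prev_short, gap_next_short):
    g1 = tau / 2 if gap_prev_short else 2 * tau
    g2 = tau / 2 if gap_next_short else 2 * tau
    return np.array([0.0, g1, g1 + g2])


class TestClassifyScenario:
    def test_all_nontarget_is_tn(self):
        for g1, g2 in product((True, False), repeat=2):
            assert rs.classify_scenario(False, False, False, g1, g2) == "TN"

    def test_scenario_7_nontarget_between_targets_is_fp(self):
        # a nontarget pushed sideways by the preceding target's actuation and
        # not pushed back (far gap long) exits through a side channel
        assert rs.classify_scenario(True, False, True, True, False) == "FP"

    def test_scenario_7_counterfactual_short_far_gap_restores_tn(self):
        # if the following target's opposite push also lands in-window it
        # returns the nontarget to the centre stream
        assert rs.classify_scenario(True, False, True, True, True) == "TN"

    def test_isolated_target_is_tp(self):
        assert rs.classify_scenario(False, True, False, False, False) == "TP"

    def test_rule_variant_divergent_case(self):
        # a target preceded by an in-window actuation: its own (opposite)
        # push cancels under alternating rules, dominates under own_dominant
        args = (True, True, False, True, False)
        assert rs.classify_scenario(*args, rule_variant="alternating") == "FN"
        assert rs.classify_scenario(*args, rule_variant="own_dominant") == "TP"

    @pytest.mark.parametrize("variant", rs.sorter.RULE_VARIANTS)
    def test_exhaustive_32_cases_match_monte_carlo_triples(self, variant):
        # oracle: the event-stream simulator run on constructed 3-particle
        # micro-streams realizing each scenario
        tau = 1.5e-3
        cfg = rs.SortTimingConfig(sort_window=2 * tau)
        for prev, self_, next_, g1, g2 in product((True, False), repeat=5):
            times = triple_times(tau, g1, g2)
            labels = np.array([prev, self_, next_])
            run = rs.simulate_sorting(times, labels, cfg, rule_variant=variant)
            expected = rs.classify_scenario(prev, self_, next_, g1, g2, variant)
            assert run.outcome[1] == expected, (prev, self_, next_, g1, g2)

    def test_unknown_variant_raises(self):
        with pytest.raises(ValueError):
            rs.classify_scenario(True, True, True, True, True, rule_variant="x")


class TestEnumerateScenarios:
    def test_row_count_is_32(self):
        table = rs.enumerate_scenarios(50.0, 1.5e-3, 0.6)
        assert len(table.scenarios) == 32

    @pytest.mark.parametrize("rate", GRID_RATES)
    @pytest.mark.parametrize("tau", GRID_TAUS)
    @pytest.mark.parametrize("r", GRID_RS)
    def test_probabilities_sum_to_one(self, rate, tau, r):
        table = rs.enumerate_scenarios(rate, tau, r)
        assert table.total_probability == pytest.approx(1.0, abs=1e-12)

    def test_pure_target_mixture_has_no_fp_mass(self):
        table = rs.enumerate_scenarios(100.0, 1.5e-3, 1.0)
        assert table.p_fp == 0.0

    def test_closed_form_tp_fp_mass(self):
        # independent algebraic oracle: under the alternating rules the
        # particle of interest is collected iff an odd number of in-window
        # actuations hits it, so with q = r*p:
        #   P_TP = r [(1-q)^2 + q^2],  P_FP = (1-r) 2q(1-q)
        rate, tau, r = 85.6, 1.5e-3, 0.6
        p = 1 - np.exp(-rate * tau)
        q = r * p
        table = rs.enumerate_scenarios(rate, tau, r)
        assert table.p_tp == pytest.approx(r * ((1 - q) ** 2 + q**2), rel=1e-12)
        assert table.p_fp == pytest.approx((1 - r) * 2 * q * (1 - q), rel=1e-12)


class TestPurityAnalytic:
    def test_vanishing_rate_gives_unit_purity(self):
        assert rs.purity_analytic(1e-12, 1.5e-3, 0.3) == pytest.approx(1.0)

    def test_pure_targets_give_unit_purity(self):
        assert rs.purity_analytic(200.0, 3e-3, 1.0) == pytest.approx(1.0)

    def test_no_targets_raises(self):
        with pytest.raises(ValueError):
            rs.purity_analytic(50.0, 1.5e-3, 0.0)

    def test_bounded_and_monotone_on_grid(self):
        for tau, r in product(GRID_TAUS, GRID_RS):
            purities = [rs.purity_analytic(lam, tau, r) for lam in GRID_RATES]
            assert all(0.0 <= p <= 1.0 for p in purities)
            assert all(a >= b - 1e-12 for a, b in zip(purities, purities[1:]))
        for lam, r in product(GRID_RATES, GRID_RS):
            purities = [rs.purity_analytic(lam, tau, r) for tau in GRID_TAUS]
            assert all(a >= b - 1e-12 for a, b in zip(purities, purities[1:]))

    def test_approaches_one_as_rate_window_product_vanishes(self):
        assert rs.purity_analytic(1.0, 1e-6, 0.5) > 1 - 1e-5

    def test_faster_flow_higher_purity_pointwise(self):
        # tau = sort_region / flow_speed / 2: doubling the flow speed halves
        # tau, so the faster-flow curve dominates at every throughput
        for lam in GRID_RATES:
            slow = rs.SortTimingConfig.from_flow(120.0, 0.02)
            fast = rs.SortTimingConfig.from_flow(120.0, 0.08)
            assert (
                rs.purity_analytic(lam, fast.tau, 0.6)
                >= rs.purity_analytic(lam, slow.tau, 0.6) - 1e-12
            )

    def test_matches_monte_carlo_at_operating_point(self):
        # oracle: simulate_sorting on 1e5 Poisson events
        rate, tau, r = 50.0, 1.5e-3, 0.6
        n = 100_000
        rng = np.random.default_rng(42)
        times = np.cumsum(rng.exponential(1 / rate, n))
        labels = rng.random(n) < r
        run = rs.simulate_sorting(times, labels, rs.SortTimingConfig(2 * tau))
        analytic = rs.purity_analytic(rate, tau, r)
        n_collected = run.counts["TP"] + run.counts["FP"]
        se = np.sqrt(analytic * (1 - analytic) / n_collected)
        assert abs(run.purity - analytic) <= 3 * se


class TestSimulateSorting:
    def test_single_isolated_target_collected_tp(self):
        run = rs.simulate_sorting([1.0], [True], rs.SortTimingConfig())
        assert run.actuated[0] and run.collected[0]
        assert run.outcome[0] == "TP"

    def test_scenario_7_triple_middle_is_fp(self):
        tau = 1.5e-3
        times = triple_times(tau, True, False)
        run = rs.simulate_sorting(
            times, [True, False, True], rs.SortTimingConfig(2 * tau)
        )
        assert run.collected[1]
        assert run.outcome[1] == "FP"

    def test_conservation_and_partition(self):
        rng = np.random.default_rng(5)
        times = np.cumsum(rng.exponential(1 / 100.0, 2000))
        labels = rng.random(2000) < 0.6
        run = rs.simulate_sorting(times, labels, rs.SortTimingConfig())
        c = run.counts
        assert sum(c.values()) == 2000
        assert np.sum(run.collected) + np.sum(~run.collected) == 2000
        # outcome consistent with (label, destination)
        assert np.all((run.outcome == "TP") == (run.is_target & run.collected))
        assert np.all((run.outcome == "FN") == (run.is_target & ~run.collected))

    def test_decisions_override_labels(self):
        # an inverted classifier sorts nontargets: isolated nontargets
        # become FP, isolated targets FN
        times = np.array([1.0, 2.0])
        labels = np.array([True, False])
        run = rs.simulate_sorting(
            times, labels, rs.SortTimingConfig(), decisions=~labels
        )
        assert run.outcome[0] == "FN" and run.outcome[1] == "FP"

    def test_unsorted_times_raise(self):
        with pytest.raises(ValueError):
            rs.simulate_sorting([2.0, 1.0], [True, True], rs.SortTimingConfig())


class TestEventRate:
    def test_constant_100_eps(self):
        times = np.arange(200) * 0.01
        series = rs.event_rate(times)
        np.testing.assert_allclose(series.rates, 100.0, rtol=1e-9)
        assert series.indices[0] == 51
        assert series.nominal_throughput == pytest.approx(100.0, abs=0.5)

    def test_one_eps_unit_case(self):
        times = np.arange(0.0, 101.0)
        series = rs.event_rate(times)
        np.testing.assert_allclose(series.rates, 1.0, rtol=1e-12)
        assert series.rates.size == 51  # e_51 .. e_101

    def test_poisson_modal_rate_near_lambda(self):
        # oracle: law of large numbers over 50-event windows
        rng = np.random.default_rng(8)
        times = np.cumsum(rng.exponential(1 / 50.0, 10_000))
        series = rs.event_rate(times)
        assert series.nominal_throughput == pytest.approx(50.0, rel=0.10)

    def test_too_few_events_raise(self):
        with pytest.raises(ValueError):
            rs.event_rate(np.arange(50.0))

    def test_non_monotone_times_raise(self):
        times = np.arange(60.0)
        times[30] = times[29]
        with pytest.raises(ValueError):
            rs.event_rate(times)


class TestPurityYield:
    def test_perfect_sort(self):
        assert rs.purity_yield(100, 0, 0) == (1.0, 1.0)

    def test_nine_one_one(self):
        purity, yield_ = rs.purity_yield(9, 1, 1)
        assert purity == pytest.approx(0.9)
        assert yield_ == pytest.approx(0.9)

    def test_inverted_gate(self):
        assert rs.purity_yield(0, 5, 10) == (0.0, 0.0)

    def test_empty_collection_purity_flagged_undefined(self):
        purity, yield_ = rs.purity_yield(0, 0, 10)
        assert np.isnan(purity)
        assert yield_ == 0.0

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            rs.purity_yield(-1, 0, 0)


class TestGatedFraction:
    def test_rare_event_percentages(self):
        assert rs.gated_fraction(26, 7786) == pytest.approx(0.334, abs=5e-4)
        assert rs.gated_fraction(20, 220_152) == pytest.approx(0.00908, abs=5e-5)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            rs.gated_fraction(1, 0)


def test_timing_config_tau_from_flow():
    cfg = rs.SortTimingConfig.from_flow(120.0, 0.04)
    assert cfg.tau == pytest.approx(1.5e-3)
    assert rs.SortTimingConfig(sort_window=3e-3).tau == pytest.approx(1.5e-3)
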