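import itertools
import math

import numpy as np
import pytest

from trialvalue import (
    Beliefs,
    EconomicParams,
    MuGrid,
    classify_prior,
    expected_positive_part,
    one_stage_design,
    preposterior_sd,
    solve_boundary,
    stop_value,
)
from trialvalue.boundary_solver import GridTooNarrowError


class TestExpectedPositivePart:
    def test_degenerate(self):
        assert expected_positive_part(5.0, 0.0) == 5.0
        assert expected_positive_part(-5.0, 0.0) == 0.0

    def test_symmetric_closed_form(self):
        assert expected_positive_part(0.0, 1.0) == pytest.approx(1.0 / math.sqrt(2 * math.pi))

    def test_against_monte_carlo(self):
        rng = np.random.default_rng(7)
        draws = np.maximum(rng.normal(-1.0, 2.0, size=1_000_000), 0.0)
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert expected_positive_part(-1.0, 2.0) == pytest.approx(draws.mean(), abs=3 * se)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            expected_positive_part(0.0, -1.0)

    def test_monotone_in_scale(self):
        """More residual uncertainty can only increase the option value."""
        for mu in (-800.0, 0.0, 1234.5):
            vals = [expected_positive_part(mu, s) for s in np.linspace(0, 50, 40)]
            assert np.all(np.diff(vals) >= -1e-12)


class TestPreposteriorSd:
    def test_no_observations_no_movement(self):
        assert preposterior_sd(2.0, 0, 10.0) == 0.0

    def test_direct_formula(self):
        assert preposterior_sd(2.0, 2, 2.0) == pytest.approx(1.0)

    def test_all_uncertainty_resolves_in_limit(self):
        assert preposterior_sd(4.0, 10**12, 10.0) == pytest.approx(10.0 / 2.0, rel=1e-5)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            preposterior_sd(0.0, 1, 10.0)
        with pytest.raises(ValueError):
            preposterior_sd(1.0, -1, 10.0)


class TestStopValue:
    def test_immediate_decision_sign_rule(self):
        """With no pipeline the stop value is P*max(mu, 0)."""
        params = EconomicParams(20_000, 1000.0, 4080.0, q_max=125, delay_tau=47)
        prior = Beliefs(0.0, 2.0, 14_000.0)
        assert stop_value(125, -100.0, params, prior) == pytest.approx(0.0)
        assert stop_value(125, 100.0, params, prior) == pytest.approx(100_000.0)

    def test_pipeline_option_value_at_zero_mean(self):
        params = EconomicParams(20_000, 1000.0, 4080.0, q_max=125, delay_tau=47)
        prior = Beliefs(0.0, 2.0, 14_000.0)
        s = preposterior_sd(2.0, 47, 14_000.0)
        expected = 1000.0 * s / math.sqrt(2 * math.pi)
        assert stop_value(0, 0.0, params, prior) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Exhaustive-policy oracle on a tiny instance
# ---------------------------------------------------------------------------

TINY_PARAMS = EconomicParams(
    wtp_lambda=20_000, pop_to_benefit=10.0, var_cost_c=0.2,
    q_max=4, delay_tau=1, block_size=1,
)
TINY_PRIOR = Beliefs(mu=0.0, m=1.0, sigma_x=1.0)
TWO_POINT = (np.array([-1.0, 1.0]), np.array([0.5, 0.5]))


def _policy_value(grid, intervals, params, prior):
    """Exact value of an interval stopping policy under the 2-point outcome.

    ``intervals[n]`` is (i_lo, i_hi) grid-index bounds of the continuation
    set at observed count n, or None for an empty set.  Terminal stop is
    forced at n = q_max - delay_tau.
    """
    mu = grid.values
    n_max = params.n_looks_max
    v = stop_value(n_max, mu, params, prior)
    for n in range(n_max - 1, -1, -1):
        step = preposterior_sd(prior.m + n, 1, prior.sigma_x)
        cont = -params.var_cost_c + 0.5 * (
            np.interp(mu + step, mu, v) + np.interp(mu - step, mu, v)
        )
        stop = stop_value(n, mu, params, prior)
        v_new = stop.copy()
        if intervals[n] is not None:
            i_lo, i_hi = intervals[n]
            v_new[i_lo : i_hi + 1] = cont[i_lo : i_hi + 1]
        v = v_new
    return v


def _all_interval_policies(n_points, n_epochs):
    per_epoch = [None] + [
        (lo, hi) for lo in range(n_points) for hi in range(lo, n_points)
    ]
    return itertools.product(per_epoch, repeat=n_epochs)


class TestDynamicProgrammingOracle:
    def test_dp_matches_exhaustive_policy_search(self):
        """Backward induction attains the best interval stopping policy."""
        grid = MuGrid(np.linspace(-2.0, 2.0, 5))
        sol = solve_boundary(
            TINY_PARAMS, TINY_PRIOR, grid, quadrature=TWO_POINT, edge_margin=0.0
        )
        best = np.full(grid.values.size, -np.inf)
        for pol in _all_interval_policies(5, TINY_PARAMS.n_looks_max):
            val = _policy_value(grid, list(pol), TINY_PARAMS, TINY_PRIOR)
            best = np.maximum(best, val)
        assert sol.value[0] == pytest.approx(best, rel=1e-12, abs=1e-12)

    def test_dp_boundary_is_an_optimal_policy(self):
        """Replaying the DP's own continuation intervals recovers its value."""
        grid = MuGrid(np.linspace(-2.0, 2.0, 5))
        sol = solve_boundary(
            TINY_PARAMS, TINY_PRIOR, grid, quadrature=TWO_POINT, edge_margin=0.0
        )
        intervals = []
        for n in range(TINY_PARAMS.n_looks_max):
            iv = sol.continuation_interval(n)
            if iv is None:
                intervals.append(None)
            else:
                inside = np.nonzero((grid.values >= iv[0]) & (grid.values <= iv[1]))[0]
                intervals.append((inside[0], inside[-1]) if inside.size else None)
        val = _policy_value(grid, intervals, TINY_PARAMS, TINY_PRIOR)
        assert sol.value[0] == pytest.approx(val, rel=1e-12, abs=1e-12)


class TestBoundaryProperties:
    def test_value_dominates_stopping(self, boundary250, config250):
        params, prior = config250.params(), config250.prior()
        mu = boundary250.grid.values
        scale = np.abs(boundary250.value).max()
        for n in (0, 25, 90, 180, params.n_looks_max):
            stop = stop_value(n, mu, params, prior)
            assert np.all(boundary250.value[n] - stop >= -1e-9 * scale)
            iv = boundary250.continuation_interval(n)
            if iv is not None:
                outside = (mu < iv[0] - boundary250.grid.spacing) | (
                    mu > iv[1] + boundary250.grid.spacing
                )
                assert boundary250.value[n][outside] == pytest.approx(
                    stop[outside], rel=1e-9, abs=1e-9 * scale
                )

    def test_value_is_convex_in_mu(self, boundary250):
        scale = np.abs(boundary250.value).max()
        for n in (0, 40, 120, 203):
            d2 = np.diff(boundary250.value[n], 2)
            assert d2.min() >= -1e-8 * scale

    def test_symmetry_with_zero_switch_cost(self, boundary250, config250):
        """V(n, mu) - P*mu = V(n, -mu), hence upper = -lower."""
        P = config250.pop_to_benefit
        mu = boundary250.grid.values
        scale = np.abs(boundary250.value).max()
        shifted = boundary250.value - P * mu[None, :]
        assert shifted == pytest.approx(boundary250.value[:, ::-1], abs=1e-7 * scale)
        ok = np.isfinite(boundary250.lower)
        assert boundary250.upper[ok] == pytest.approx(
            -boundary250.lower[ok], abs=boundary250.grid.spacing
        )

    def test_continuation_empty_at_horizon(self, boundary250, config250):
        n_max = config250.params().n_looks_max
        assert boundary250.continuation_interval(n_max) is None
        assert math.isnan(boundary250.lower[n_max])

    def test_continuation_is_interval_and_contains_prior_mean(self, boundary250):
        """At early looks the near non-informative prior sits inside the region."""
        lo, hi = boundary250.continuation_interval(0)
        assert lo < 0.0 < hi

    def test_allocations_and_plot_coordinate(self, boundary250, config250):
        params, prior = config250.params(), config250.prior()
        assert boundary250.allocations[0] == params.delay_tau
        assert boundary250.allocations[-1] == params.q_max
        assert boundary250.plot_coordinate[0] == prior.m + params.delay_tau

    def test_doubling_qmax_barely_moves_early_boundary(self, boundary125, boundary250):
        """The extra recruitment headroom matters only near the closing cone."""
        n = np.arange(0, 61)  # allocations up to 107 of the 125-pair design
        diff = np.abs(boundary250.lower[n] - boundary125.lower[n])
        height = np.nanmax(np.abs(boundary125.lower))
        assert np.nanmax(diff) <= 0.15 * height

    def test_sampling_never_pays_with_huge_cost(self, config250):
        params = EconomicParams(
            20_000, config250.pop_to_benefit, 1e12,
            q_max=config250.q_max, delay_tau=config250.delay_tau,
        )
        sol = solve_boundary(params, config250.prior(), config250.grid())
        assert np.all(np.isnan(sol.lower))

    def test_narrow_grid_rejected(self, config250):
        grid = MuGrid(np.linspace(-3000.0, 3000.0, 101))
        with pytest.raises(GridTooNarrowError):
            solve_boundary(config250.params(), config250.prior(), grid)


class TestOneStageDesign:
    def test_free_information_takes_maximum(self, config250):
        params = EconomicParams(
            20_000, config250.pop_to_benefit, 0.0,
            q_max=config250.q_max, delay_tau=config250.delay_tau,
        )
        n_star, _ = one_stage_design(params, config250.prior())
        assert n_star == params.delay_tau - 1

    def test_negligible_population_no_trial(self, config250):
        params = EconomicParams(
            20_000, 1e-9, 4080.0, q_max=250, delay_tau=47
        )
        n_star, value = one_stage_design(params, config250.prior())
        assert n_star == 0
        assert value == pytest.approx(0.0)

    def test_value_accounts_for_sampling_cost(self, config250):
        params, prior = config250.params(), config250.prior()
        n_star, value = one_stage_design(params, prior)
        assert 1 <= n_star < params.delay_tau
        s = preposterior_sd(prior.m, n_star, prior.sigma_x)
        direct = (
            params.pop_to_benefit * expected_positive_part(prior.mu, s)
            - params.var_cost_c * n_star
        )
        assert value == pytest.approx(direct)


class TestClassifyPrior:
    def test_default_prior_runs_sequential(self, config250, boundary250):
        choice = classify_prior(config250.params(), config250.prior(), boundary250)
        assert choice.label == "sequential"
        a, b, c, d = choice.thresholds_abcd
        assert b <= c <= 0.0 <= d <= a

    def test_extreme_prior_adopts_without_trial(self, config250, boundary250):
        params = config250.params()
        strong = Beliefs(mu=45_000.0, m=2.0, sigma_x=config250.sigma_x)
        assert classify_prior(params, strong, boundary250).label == "adopt_new_no_trial"
        weak = Beliefs(mu=-45_000.0, m=2.0, sigma_x=config250.sigma_x)
        assert classify_prior(params, weak, boundary250).label == "adopt_std_no_trial"

    def test_thresholds_agree_with_dense_sweep(self, config250, boundary250):
        params, prior = config250.params(), config250.prior()
        a, b, c, d = classify_prior(params, prior, boundary250).thresholds_abcd
        margin = 1000.0
        for mu0 in np.linspace(b - 8000.0, a + 8000.0, 41):
            if min(abs(mu0 - t) for t in (a, b, c, d)) < margin:
                continue
            label = classify_prior(
                params, Beliefs(float(mu0), prior.m, prior.sigma_x), boundary250
            ).label
            if mu0 > a:
                assert label == "adopt_new_no_trial"
            elif mu0 < b:
                assert label == "adopt_std_no_trial"
            elif c < mu0 < d:
                assert label == "sequential"
            else:
                assert label == "one_stage"
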