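"""Unit and property tests for the decision-theoretic core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import conflictbdt as cb
from conflictbdt.model import DecisionModel, UtilityParams


def brute_force_optimum(model, interval, resolution=1e-3):
    """Independent maximiser oracle: plain argmax on a dense grid."""
    grid = np.arange(interval[0], interval[1] + 0.5 * resolution, resolution)
    z = cb.expected_utility(grid, model)
    return float(grid[np.argmax(z)])


def make_scenario2_model(gain=1.0, loss=-2.0, lambda1=0.8, baseline=0.62,
                         a0=-1.2, a1=1.5, scale=1.0):
    prior = cb.quadratic_threat_prior(baseline, a0, a1)
    return DecisionModel(
        utilities=UtilityParams(gain=gain, loss=loss),
        gain_prior=cb.GainPrior(rate=lambda1),
        threat=prior,
        threat_scale=scale,
    )


class TestGainPrior:
    def test_survival_at_zero_is_one(self, gain_prior):
        assert cb.gain_probability(0.0, gain_prior) == 1.0

    def test_mean_lifetime_point_matches_numerical_integration(self, gain_prior):
        # survival at the mean lifetime: closed form vs integrating the density
        expected, _ = quad(lambda t: 0.8 * math.exp(-0.8 * t), 1.25, np.inf)
        assert cb.gain_probability(1.25, gain_prior) == pytest.approx(expected, rel=1e-10)
        assert cb.gain_probability(1.25, gain_prior) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_half_life(self, gain_prior):
        assert cb.gain_probability(math.log(2) / 0.8, gain_prior) == pytest.approx(0.5)

    def test_negative_latency_rejected(self, gain_prior):
        with pytest.raises(ValueError):
            cb.gain_probability(-0.1, gain_prior)


class TestPoissonThreat:
    def test_no_exposure_no_risk(self):
        assert cb.exposure_loss_probability(0.0, cb.PoissonThreat(2.0)) == 0.0

    @pytest.mark.parametrize("rate, p", [(1.0536, 0.1), (2.2314, 0.2), (3.5667, 0.3)])
    def test_design_exposure_probabilities(self, rate, p):
        assert cb.exposure_loss_probability(0.1, cb.PoissonThreat(rate)) == pytest.approx(
            p, abs=5e-5
        )

    def test_negative_exposure_rejected(self):
        with pytest.raises(ValueError):
            cb.exposure_loss_probability(-0.1, cb.PoissonThreat(1.0))


class TestRateFromCatchProbability:
    @pytest.mark.parametrize(
        "p, expected", [(0.1, 1.0536), (0.2, 2.2314), (0.3, 3.5667)]
    )
    def test_printed_design_rates(self, p, expected):
        assert cb.rate_from_catch_probability(p, 0.1) == pytest.approx(expected, abs=5e-5)

    def test_small_probability_linearisation(self):
        p = 1e-8
        assert cb.rate_from_catch_probability(p, 0.1) == pytest.approx(p / 0.1, rel=1e-6)

    def test_inverse_of_exposure_probability(self):
        rate = cb.rate_from_catch_probability(0.25, 0.3)
        assert cb.exposure_loss_probability(0.3, cb.PoissonThreat(rate)) == pytest.approx(0.25)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            cb.rate_from_catch_probability(p, 0.1)


class TestExpectedUtility:
    def test_reduces_to_gain_when_threat_never_fires(self, gain_prior):
        prior = cb.quadratic_threat_prior(0.0, -0.0001, 1.0)  # flat ~zero prior
        m = DecisionModel(UtilityParams(1.0, -1.0), gain_prior, prior)
        t = np.linspace(0, 2, 20)
        np.testing.assert_allclose(
            cb.expected_utility(t, m), cb.gain_probability(t, gain_prior), atol=1e-12
        )

    def test_objective_statistics_give_decreasing_utility(self, gain_prior):
        m = DecisionModel(
            UtilityParams(1.3, -2.0), gain_prior, cb.PoissonThreat(2.2314), delta_t=0.1
        )
        t = np.linspace(0, 3, 300)
        assert np.all(np.diff(cb.expected_utility(t, m)) < 0)

    def test_subjective_prior_gives_interior_maximum(self):
        m = make_scenario2_model()
        t = np.linspace(0, 2, 2001)
        z = cb.expected_utility(t, m)
        i = np.argmax(z)
        assert 0 < i < len(t) - 1


class TestUtilityDerivative:
    def test_objective_statistics_closed_form(self, gain_prior):
        m = DecisionModel(
            UtilityParams(2.0, -1.0), gain_prior, cb.PoissonThreat(1.0536), delta_t=0.1
        )
        for t in (0.0, 0.3, 1.7):
            assert cb.utility_derivative(t, m) == pytest.approx(
                -2.0 * 0.8 * math.exp(-0.8 * t), rel=1e-12
            )

    def test_zero_at_interior_optimum(self):
        m = make_scenario2_model()
        opt = cb.optimal_latency(m)
        assert not opt.boundary
        assert cb.utility_derivative(opt.t1, m) == pytest.approx(0.0, abs=1e-9)

    def test_sign_change_across_optimum(self):
        m = make_scenario2_model()
        opt = cb.optimal_latency(m)
        before = np.linspace(0.01, opt.t1 - 0.02, 10)
        after = np.linspace(opt.t1 + 0.02, opt.t1 + 0.1, 10)
        assert np.all(cb.utility_derivative(before, m) > 0)
        assert np.all(cb.utility_derivative(after, m) < 0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        gain=st.floats(0.5, 5.0),
        loss=st.floats(-5.0, -0.5),
        lambda1=st.floats(0.2, 2.0),
        a0=st.floats(-2.0, -0.5),
        a1=st.floats(0.5, 3.0),
        frac=st.floats(0.05, 0.9),
    )
    def test_matches_finite_differences(self, gain, loss, lambda1, a0, a1, frac):
        """Analytic derivative agrees with central differences to 1e-6 relative."""
        drop = a0**2 / (2 * a1)
        baseline = min(0.95, drop + 0.04 + 0.5 * (0.95 - min(drop + 0.04, 0.95)))
        if baseline <= drop + 0.02:
            return  # prior would hit the [0,1] clip inside the range probed
        m = make_scenario2_model(gain, loss, lambda1, baseline, a0, a1)
        t_clamp = -a0 / a1
        t = frac * 0.95 * t_clamp
        h = 1e-5
        fd = (cb.expected_utility(t + h, m) - cb.expected_utility(t - h, m)) / (2 * h)
        an = cb.utility_derivative(t, m)
        assert an == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_finite_differences_for_objective_and_motor_cost_models(self, gain_prior):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = DecisionModel(
                UtilityParams(rng.uniform(0.5, 3), -rng.uniform(0.5, 3)),
                gain_prior,
                cb.PoissonThreat(rng.uniform(0.5, 4)),
                delta_t=rng.uniform(0.05, 0.3),
                motor_cost=cb.MotorCost(rng.uniform(0, 1), rng.uniform(0.5, 5)),
            )
            t = rng.uniform(0.05, 2.0)
            h = 1e-5
            fd = (cb.expected_utility(t + h, m) - cb.expected_utility(t - h, m)) / (2 * h)
            assert cb.utility_derivative(t, m) == pytest.approx(fd, rel=1e-6, abs=1e-9)


class TestOptimalLatency:
    def test_objective_statistics_move_asap(self, gain_prior):
        m = DecisionModel(
            UtilityParams(1.0, -1.0), gain_prior, cb.PoissonThreat(1.0536), delta_t=0.1
        )
        opt = cb.optimal_latency(m, interval=(0.15, 2.0))
        assert opt.t1 == pytest.approx(0.15)
        assert opt.boundary

    def test_boundary_optimality_over_random_parameters(self):
        """Under objective task statistics the left endpoint always wins."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = DecisionModel(
                UtilityParams(rng.uniform(0.2, 5), -rng.uniform(0.2, 5)),
                cb.GainPrior(rate=rng.uniform(0.2, 3)),
                cb.PoissonThreat(rng.uniform(0.3, 5)),
                delta_t=rng.uniform(0.02, 0.5),
            )
            lo = rng.uniform(0.0, 0.5)
            hi = lo + rng.uniform(0.5, 3.0)
            opt = cb.optimal_latency(m, interval=(lo, hi), resolution=5e-3)
            assert opt.t1 == pytest.approx(lo)
            assert opt.boundary

    def test_interior_maximiser_with_negative_curvature(self):
        m = make_scenario2_model()
        opt = cb.optimal_latency(m)
        assert not opt.boundary
        h = 1e-4
        curvature = (
            cb.expected_utility(opt.t1 + h, m)
            - 2 * cb.expected_utility(opt.t1, m)
            + cb.expected_utility(opt.t1 - h, m)
        ) / h**2
        assert curvature < 0

    def test_grid_refinement_stability(self):
        m = make_scenario2_model(loss=-3.0)
        coarse = cb.optimal_latency(m, resolution=4e-3).t1
        fine = cb.optimal_latency(m, resolution=2e-3).t1
        assert abs(fine - coarse) < 4e-3

    def test_matches_brute_force_oracle(self):
        m = make_scenario2_model(loss=-2.5, scale=1.2)
        opt = cb.optimal_latency(m)
        assert abs(opt.t1 - brute_force_optimum(m, (0.0, 5.0))) <= 1.1e-3


class TestVerifyAssumptions:
    def test_exposure_only_threat_has_no_decay(self, gain_prior):
        m = DecisionModel(
            UtilityParams(1.0, -1.0), gain_prior, cb.PoissonThreat(2.0), delta_t=0.1
        )
        rep = cb.verify_assumptions(m, (0.0, 1.0))
        assert not rep.threat_decreasing
        assert rep.gain_decreasing

    def test_example_prior_satisfies_all_conditions(self):
        m = make_scenario2_model()
        rep = cb.verify_assumptions(m, (0.0, 0.75))
        assert rep.all_hold()
        opt = cb.optimal_latency(m, (0.0, 0.75))
        assert not opt.boundary
        assert cb.utility_derivative(opt.t1 - 0.01, m) > 0 > cb.utility_derivative(
            opt.t1 + 0.01, m
        )

    def test_slowly_decaying_threat_fails_crossing_and_gives_boundary(self, gain_prior):
        # threat decays much slower than the gain: derivative never positive
        prior = cb.quadratic_threat_prior(0.9, -0.05, 0.01, support=(0.0, 5.0))
        m = DecisionModel(UtilityParams(1.0, -1.0), gain_prior, prior)
        rep = cb.verify_assumptions(m, (0.0, 2.0))
        assert not rep.derivative_crossing
        assert cb.optimal_latency(m, (0.0, 2.0)).boundary


class TestLatencyShiftUnderScaling:
    def test_identity_scaling(self):
        m = make_scenario2_model()
        assert cb.latency_shift_under_scaling(m, 1.0, "loss_magnitude") == 0.0

    @pytest.mark.parametrize("mode", ["loss_magnitude", "loss_probability"])
    @pytest.mark.parametrize("k", [1.05, 1.1, 1.2])
    def test_larger_threat_delays_approach(self, mode, k):
        """Comparative statics against the 1 ms brute-force grid oracle."""
        m = make_scenario2_model(loss=-2.0)
        shift = cb.latency_shift_under_scaling(m, k, mode)
        assert shift >= 0.0
        if mode == "loss_magnitude":
            scaled = make_scenario2_model(loss=-2.0 * k)
        else:
            scaled = make_scenario2_model(loss=-2.0, scale=k)
        oracle = brute_force_optimum(scaled, (0.0, 5.0)) - brute_force_optimum(
            m, (0.0, 5.0)
        )
        assert oracle >= -1e-9
        assert shift == pytest.approx(oracle, abs=2.1e-3)

    def test_motor_cost_optimum_ignores_loss_but_not_gain(self, gain_prior):
        m = DecisionModel(
            UtilityParams(1.0, -1.0),
            gain_prior,
            cb.PoissonThreat(1.0536),
            delta_t=0.1,
            motor_cost=cb.MotorCost(c0=0.5, decay=3.0),
        )
        base = cb.optimal_latency(m, (0.0, 2.0))
        assert not base.boundary  # the cost alone creates an interior optimum
        assert cb.latency_shift_under_scaling(m, 1.2, "loss_magnitude", (0.0, 2.0)) == 0.0
        assert cb.latency_shift_under_scaling(m, 1.2, "loss_probability", (0.0, 2.0)) == 0.0
        bigger_gain = DecisionModel(
            UtilityParams(2.0, -1.0), gain_prior, cb.PoissonThreat(1.0536),
            delta_t=0.1, motor_cost=cb.MotorCost(c0=0.5, decay=3.0),
        )
        assert cb.optimal_latency(bigger_gain, (0.0, 2.0)).t1 != pytest.approx(base.t1, abs=1e-3)

    def test_probability_cap_raises(self):
        m = make_scenario2_model(baseline=0.9)
        with pytest.raises(cb.ScalingError):
            cb.latency_shift_under_scaling(m, 1.5, "loss_probability")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            cb.latency_shift_under_scaling(make_scenario2_model(), 1.1, "nonsense")


class TestValidation:
    def test_utility_signs_enforced(self):
        with pytest.raises(ValueError):
            UtilityParams(gain=-1.0, loss=-1.0)
        with pytest.raises(ValueError):
            UtilityParams(gain=1.0, loss=0.5)

    def test_prior_domain_enforced(self):
        m = make_scenario2_model()
        with pytest.raises(ValueError):
            cb.expected_utility(7.0, m)  # outside the prior's support
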