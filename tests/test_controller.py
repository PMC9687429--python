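"""Adaptive RBF controller: activations, control law, projection learning."""

import math

import numpy as np
import pytest

from aidsim import (
    HYBRID_ETA_SCHEDULE,
    SCRATCH_ETA_SCHEDULE,
    ControllerConfig,
    RBFNetwork,
    activations,
    control_action,
    disturbance_estimate,
    learning_rate,
    pretrain_from_basal,
    update_weights,
)
from aidsim.errors import InvalidInputError

THETA = 3.0e4


class TestActivations:
    def test_unit_activation_at_centers(self, network):
        phi0 = activations(0.0, network)
        assert phi0[5] == 1.0  # center 0.0
        phi100 = activations(100.0, network)
        assert phi100[10] == 1.0  # center 100.0

    def test_one_width_from_center(self, network):
        for j, (c, l) in enumerate(zip(network.centers, network.widths)):
            phi = activations(c + l, network)
            assert phi[j] == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_all_in_unit_interval(self, network):
        # mathematically (0, 1]; far tails may underflow to exactly 0
        for x in np.linspace(-300.0, 300.0, 61):
            phi = activations(float(x), network)
            assert np.all(phi >= 0.0) and np.all(phi <= 1.0)
            assert phi.max() > 0.0
        near = activations(12.0, network)
        assert np.all(near > 0.0)

    def test_nonfinite_error_rejected(self, network):
        with pytest.raises(InvalidInputError):
            activations(float("nan"), network)


class TestDisturbanceEstimate:
    def test_linear_in_weights(self, network):
        assert disturbance_estimate(12.0, network) == 0.0
        for j in range(network.size):
            w = np.zeros(network.size)
            w[j] = 1.0
            unit = RBFNetwork(network.centers, network.widths, w)
            phi = activations(12.0, network)
            assert disturbance_estimate(12.0, unit) == pytest.approx(phi[j])
            double = RBFNetwork(network.centers, network.widths, 2.0 * w)
            assert disturbance_estimate(12.0, double) == pytest.approx(2.0 * phi[j])


class TestControlAction:
    def test_identity_at_zero_error(self):
        cfg = ControllerConfig()
        assert control_action(0.0, 0.0, cfg) == 0.0
        assert control_action(0.0, 34_722.2, cfg) == pytest.approx(34_722.2)

    def test_negative_command_clamped_at_pump_floor(self):
        cfg = ControllerConfig(lam=1.0)
        assert control_action(-50.0, 10.0, cfg) == 0.0  # raw -40 -> u_min

    def test_upper_actuation_limit(self):
        cfg = ControllerConfig(u_max=1000.0)
        assert control_action(100.0, 5000.0, cfg) == 1000.0

    def test_monotone_in_error(self):
        cfg = ControllerConfig()
        us = [control_action(float(x), 20_000.0, cfg)
              for x in np.linspace(-100.0, 150.0, 101)]
        assert all(b >= a for a, b in zip(us, us[1:]))

    def test_literal_gain_sign_flips_feedback(self):
        literal = ControllerConfig(literal_gain_sign=True, u_min=-1e9)
        assert control_action(30.0, 100.0, literal) == pytest.approx(-130.0)


class TestLearningRate:
    @pytest.mark.parametrize("day,eta", [
        (1, 0.50), (2, 0.10), (3, 0.10), (4, 0.05), (7, 0.05),
        (8, 0.01), (30, 0.01),
    ])
    def test_scratch_schedule(self, day, eta):
        assert learning_rate(day, SCRATCH_ETA_SCHEDULE) == eta

    @pytest.mark.parametrize("day,eta", [
        (1, 0.0), (3, 0.0), (4, 0.50), (5, 0.10), (6, 0.10),
        (7, 0.05), (8, 0.01), (63, 0.01),
    ])
    def test_hybrid_schedule(self, day, eta):
        assert learning_rate(day, HYBRID_ETA_SCHEDULE) == eta

    def test_day_below_one_rejected(self):
        with pytest.raises(InvalidInputError):
            learning_rate(0, SCRATCH_ETA_SCHEDULE)


class TestWeightUpdate:
    def test_zero_error_leaves_weights(self, network):
        net = RBFNetwork(weights=np.full(11, 7.0))
        out = update_weights(net, 0.0, 0.5, 5.0, THETA)
        assert np.array_equal(out.weights, net.weights)

    def test_interior_euler_step(self, network):
        # dw = eta * x_err * phi * dt componentwise inside the ball
        out = update_weights(network, 10.0, 0.5, 5.0, THETA)
        expected = 0.5 * 10.0 * 5.0 * activations(10.0, network)
        assert out.weights == pytest.approx(expected, rel=1e-12)

    def test_boundary_projection_is_tangential(self, network):
        w = np.zeros(11)
        w[8] = THETA  # on the boundary, aligned with a positive-error neuron
        net = RBFNetwork(network.centers, network.widths, w)
        out = update_weights(net, 20.0, 0.5, 5.0, THETA)  # outward raw update
        # norm preserved on the boundary ...
        assert np.linalg.norm(out.weights) == pytest.approx(THETA, rel=1e-9)
        # ... while the state moved along it: mass shifts from the
        # aligned neuron to the other activated neurons, never outward
        assert not np.array_equal(out.weights, w)
        assert out.weights[8] < THETA
        assert float(w @ (out.weights - w)) <= 0.0
        # tangential projection: the raw step has no component along w,
        # so directly verify (I - ww^T/w^Tw) raw  is orthogonal to w
        raw = 0.5 * 20.0 * 5.0 * activations(20.0, net)
        tangential = raw - (w @ raw) / (w @ w) * w
        assert abs(float(w @ tangential)) <= 1e-9 * THETA * np.linalg.norm(tangential)

    def test_inward_update_allowed_on_boundary(self, network):
        w = np.zeros(11)
        w[8] = THETA
        net = RBFNetwork(network.centers, network.widths, w)
        out = update_weights(net, -20.0, 0.5, 5.0, THETA)  # inward: full step
        expected = w + 0.5 * (-20.0) * 5.0 * activations(-20.0, network)
        assert out.weights == pytest.approx(expected, rel=1e-12)

    def test_norm_bounded_over_fuzzed_updates(self, network):
        rng = np.random.default_rng(0)
        net = network
        worst = 0.0
        for _ in range(100_000):
            x = rng.uniform(-150.0, 150.0)
            eta = rng.choice([0.01, 0.05, 0.1, 0.5])
            net = update_weights(net, float(x), float(eta), 5.0, THETA)
            worst = max(worst, float(np.linalg.norm(net.weights)))
        assert worst <= THETA * (1.0 + 1e-12)
        assert worst > 0.9 * THETA  # the bound was actually exercised

    def test_discrete_updates_converge_to_continuous_rule(self, network):
        # integrate dw/dt = eta*x(t)*phi(x(t)) on a fixed error profile
        # and check the per-sample Euler chain approaches it as dt -> 0
        eta, t_end = 0.05, 300.0

        def x_of(t):
            return 40.0 * math.sin(0.01 * t)

        def chain(dt):
            net = RBFNetwork()
            n = round(t_end / dt)
            for k in range(n):
                net = update_weights(net, x_of(k * dt), eta, dt, 1e12)
            return net.weights

        ref = chain(0.001)
        err_coarse = np.linalg.norm(chain(0.5) - ref)
        err_fine = np.linalg.norm(chain(0.05) - ref)
        assert err_fine < err_coarse / 5.0
        assert err_fine < 1e-3 * np.linalg.norm(ref)


class TestPretraining:
    def test_recovers_known_weights(self, network):
        rng = np.random.default_rng(4)
        w_true = rng.normal(0.0, 2000.0, 11)
        truth = RBFNetwork(network.centers, network.widths, w_true)
        cfg = ControllerConfig()
        xs = np.linspace(-40.0, 120.0, 60)
        # infusions an ideal (unclamped) pump would record for this network
        samples = [
            (float(x), cfg.lam * x + disturbance_estimate(float(x), truth))
            for x in xs
        ]
        fitted = pretrain_from_basal(samples, RBFNetwork(), cfg)
        assert fitted.weights == pytest.approx(w_true, abs=1e-6 * np.abs(w_true).max())

    def test_identical_samples_min_norm_exact_fit(self, network):
        cfg = ControllerConfig()
        samples = [(5.0, 20_000.0)] * 25  # rank-1 design
        fitted = pretrain_from_basal(samples, network, cfg)
        replay = control_action(5.0, disturbance_estimate(5.0, fitted), cfg)
        assert replay == pytest.approx(20_000.0, rel=1e-9)

    def test_constant_basal_at_zero_error(self, network):
        cfg = ControllerConfig()
        fitted = pretrain_from_basal([(0.0, 25_000.0)] * 10, network, cfg)
        assert disturbance_estimate(0.0, fitted) == pytest.approx(25_000.0, rel=1e-9)

    def test_norm_bound_respected_without_destroying_fit(self, network):
        # a near-constant high-insulin policy needs a large-norm
        # min-norm solution; the constrained fit must sit on the bound
        # and still reproduce the policy
        cfg = ControllerConfig()
        xs = np.linspace(-30.0, 80.0, 200)
        samples = [(float(x), 34_722.2) for x in xs]
        fitted = pretrain_from_basal(samples, network, cfg)
        assert np.linalg.norm(fitted.weights) <= cfg.theta_bound * (1 + 1e-9)
        replayed = [control_action(float(x), disturbance_estimate(float(x), fitted), cfg)
                    for x in xs]
        assert np.median(np.abs(np.array(replayed) - 34_722.2)) < 0.02 * 34_722.2

    def test_empty_samples_rejected(self, network):
        with pytest.raises(InvalidInputError):
            pretrain_from_basal([], network, ControllerConfig())
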