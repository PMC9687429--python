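"""Model-free adaptive glucose controller with an RBF disturbance estimator.

The plant seen by the controller is the scalar uncertainty model
``dx/dt = f + b*u + d`` with ``x`` the measured blood glucose, ``u`` the
insulin infusion and ``d`` a lumped disturbance covering meals and all
unmodelled insulin-glucose dynamics.  Feedback linearization with the
assumed-model choices ``f_hat = 0`` and a constant glycemic target gives
the control law

    u = lam * x_err + d_hat,        x_err = G - x_d,

where ``d_hat = w . phi(x_err)`` is the output of a Gaussian radial
basis function network with 11 neurons placed along the control-error
axis.  The weights adapt online by the Lyapunov-derived gradient rule
``dw/dt = eta * x_err * phi(x_err)``, wrapped in a projection operator
that keeps ``||w||_2`` within a hard bound ``theta`` -- the safety
mechanism against runaway insulin commands.  Because insulin lowers
glucose the true input gain is negative; the law above uses the
stabilizing sign convention (effective ``b_hat = -1``), with the literal
``b_hat = +1`` variant available behind a config flag for comparison.

A pseudoinverse least-squares fit (:func:`pretrain_from_basal`) can
initialize the weights from recorded basal-therapy data instead of
learning from scratch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

#: Default Gaussian centers [mg/dL] on the control-error axis.  The grid
#: is dense around zero and on the mild-hypoglycemia side (negative
#: errors) and stretches far into hyperglycemia.
DEFAULT_CENTERS: tuple[float, ...] = (
    -25.0, -10.0, -8.0, -5.0, -2.0, 0.0, 5.0, 10.0, 20.0, 40.0, 100.0,
)

#: Default Gaussian widths [mg/dL], matched index-wise to the centers.
DEFAULT_WIDTHS: tuple[float, ...] = (
    20.0, 15.0, 10.0, 8.0, 5.0, 5.0, 5.0, 20.0, 40.0, 100.0, 200.0,
)

#: Learning-rate schedule for scratch initialization: high on day 1 so
#: the network can identify insulin action and the dietary pattern, then
#: tapering to a small maintenance rate.  Entries are (first day, rate).
SCRATCH_ETA_SCHEDULE: tuple[tuple[int, float], ...] = (
    (1, 0.50), (2, 0.10), (4, 0.05), (8, 0.01),
)

#: Learning-rate schedule for the hybrid protocol: the adaptive law is
#: inactive during the 3 basal-therapy days, then follows the same taper
#: shifted to start on day 4.
HYBRID_ETA_SCHEDULE: tuple[tuple[int, float], ...] = (
    (1, 0.0), (4, 0.50), (5, 0.10), (7, 0.05), (8, 0.01),
)


@dataclass
class RBFNetwork:
    """Gaussian RBF disturbance estimator.

    ``centers`` and ``widths`` [mg/dL] define the Gaussian activations
    on the control-error axis; ``weights`` [uU/min scale] are the
    adaptive output weights.
    """

    centers: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_CENTERS))
    widths: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_WIDTHS))
    weights: np.ndarray = field(
        default_factory=lambda: np.zeros(len(DEFAULT_CENTERS)))

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (self.centers.shape == self.widths.shape == self.weights.shape):
            raise InvalidInputError("centers, widths and weights must share a shape")
        if self.centers.ndim != 1 or self.centers.size == 0:
            raise InvalidInputError("network must have a 1-D, non-empty layout")
        if np.any(self.widths <= 0.0) or not np.all(np.isfinite(self.widths)):
            raise InvalidInputError("widths must be strictly positive and finite")

    @property
    def size(self) -> int:
        return self.centers.size

    @property
    def weight_norm(self) -> float:
        return float(np.linalg.norm(self.weights))

    def copy(self) -> "RBFNetwork":
        return RBFNetwork(self.centers.copy(), self.widths.copy(), self.weights.copy())


@dataclass(frozen=True)
class ControllerConfig:
    """Gains, bounds and schedules of the adaptive controller.

    ``x_d`` target glycemia [mg/dL]; ``lam`` feedback gain [1/min];
    ``theta_bound`` hard cap on ``||w||_2``; ``sample_period`` CGM /
    actuation period [min]; ``eta_schedule`` piecewise-constant learning
    rates as (first day, rate) pairs (``None`` -> chosen per protocol);
    ``f_hat`` assumed drift term (0 for the model-free design);
    ``literal_gain_sign`` selects the destabilizing literal ``b_hat=+1``
    convention instead of the default stabilizing one; ``u_min``/``u_max``
    actuation limits [uU/min] (a pump cannot infuse negatively).
    """

    x_d: float = 110.0
    lam: float = 1.0
    theta_bound: float = 3.0e4
    sample_period: float = 5.0
    eta_schedule: tuple[tuple[int, float], ...] | None = None
    f_hat: float = 0.0
    literal_gain_sign: bool = False
    u_min: float = 0.0
    u_max: float | None = None

    def __post_init__(self) -> None:
        if self.lam <= 0.0:
            raise InvalidInputError(f"lam must be > 0, got {self.lam!r}")
        if self.theta_bound <= 0.0:
            raise InvalidInputError(f"theta_bound must be > 0, got {self.theta_bound!r}")
        if self.sample_period <= 0.0:
            raise InvalidInputError(
                f"sample_period must be > 0, got {self.sample_period!r}")
        if self.u_max is not None and self.u_max < self.u_min:
            raise InvalidInputError("u_max must be >= u_min")
        if self.eta_schedule is not None:
            days = [d for d, _ in self.eta_schedule]
            if not days or days != sorted(days) or days[0] < 1:
                raise InvalidInputError(
                    "eta_schedule must be (day, rate) pairs with days "
                    "ascending from >= 1")


def activations(x_err: float, network: RBFNetwork) -> np.ndarray:
    """Gaussian activations ``exp(-((x_err - c)/l)^2 / 2)``, each in (0, 1]."""
    if not math.isfinite(x_err):
        raise InvalidInputError(f"control error must be finite, got {x_err!r}")
    z = (x_err - network.centers) / network.widths
    return np.exp(-0.5 * z * z)


def disturbance_estimate(x_err: float, network: RBFNetwork) -> float:
    """Network output ``w . phi(x_err)`` [uU/min]; linear in the weights."""
    return float(network.weights @ activations(x_err, network))


def control_action(x_err: float, d_hat: float, config: ControllerConfig) -> float:
    """Insulin command [uU/min] for error ``x_err`` and estimate ``d_hat``.

    Evaluates ``u = b_hat^-1 * (-f_hat + dx_d/dt - lam*x_err - d_hat)``
    with a constant target (``dx_d/dt = 0``).  Under the default
    stabilizing convention (``b_hat = -1``) this is
    ``lam*x_err + d_hat - f_hat``.  The raw command is clamped to
    ``[u_min, u_max]``; clamping is logged at debug level.
    """
    if not (math.isfinite(x_err) and math.isfinite(d_hat)):
        raise InvalidInputError("control inputs must be finite")
    b_hat = 1.0 if config.literal_gain_sign else -1.0
    raw = (-config.f_hat - config.lam * x_err - d_hat) / b_hat
    u = raw
    if u < config.u_min:
        u = config.u_min
    if config.u_max is not None and u > config.u_max:
        u = config.u_max
    if u != raw:
        logger.debug("clamped insulin command %.4g -> %.4g uU/min", raw, u)
    return u


def learning_rate(
    day_index: int, schedule: Sequence[tuple[int, float]]
) -> float:
    """Piecewise-constant learning rate for a 1-based protocol day.

    Days before the first schedule entry (e.g. basal-therapy days in the
    hybrid protocol) get rate 0, i.e. no adaptation.
    """
    if day_index < 1:
        raise InvalidInputError(f"day_index must be >= 1, got {day_index!r}")
    eta = 0.0
    for first_day, rate in schedule:
        if day_index >= first_day:
            eta = rate
        else:
            break
    return eta


def update_weights(
    network: RBFNetwork,
    x_err: float,
    eta: float,
    dt_sample: float,
    theta_bound: float,
) -> RBFNetwork:
    """One discrete projection-guarded adaptation step.

    Euler discretization of ``dw/dt = eta * x_err * phi(x_err)`` over one
    control sample: ``dw = eta * x_err * phi * dt_sample``.  Inside the
    norm ball ``||w||_2 < theta_bound``, or on its boundary with the raw
    update pointing inward, the raw step is applied; otherwise only the
    component tangential to the boundary, ``(I - w w^T / w^T w) dw``, is
    kept.  The post-update norm never exceeds the bound (renormalized if
    discretization overshoots).
    """
    if dt_sample <= 0.0 or theta_bound <= 0.0:
        raise InvalidInputError("dt_sample and theta_bound must be > 0")
    w = network.weights
    phi = activations(x_err, network)
    raw = eta * x_err * dt_sample * phi
    norm = float(np.linalg.norm(w))
    on_boundary = norm >= theta_bound * (1.0 - 1e-12)
    if not on_boundary or eta * x_err * float(w @ phi) < 0.0:
        w_new = w + raw
    else:
        w_new = w + raw - (w @ raw) / (w @ w) * w
    new_norm = float(np.linalg.norm(w_new))
    if new_norm > theta_bound:
        w_new = w_new * (theta_bound / new_norm)
    return RBFNetwork(network.centers, network.widths, w_new)


def pretrain_from_basal(
    samples: Sequence[tuple[float, float]],
    network: RBFNetwork,
    config: ControllerConfig,
) -> RBFNetwork:
    """Offline pseudoinverse fit of the weights to basal-therapy records.

    ``samples`` are (control error, recorded infusion) pairs collected
    under constant basal therapy.  The regression targets are the
    disturbance values the network must output so that
    :func:`control_action` replays each recorded infusion:
    ``d_j = u_j - lam * x_err_j`` under the stabilizing convention.

    The weights are the minimum-norm least-squares solution.  When that
    solution violates the projection bound ``||w||_2 <= theta_bound``
    (narrow, non-partition-of-unity Gaussians need large coefficients to
    represent a near-constant basal requirement), the fit is shrunk onto
    the bound by Tikhonov regularization: the smallest ridge parameter
    whose solution has norm ``theta_bound`` (logged).  Unlike a plain
    rescaling of the weight vector -- which would scale the network
    *output* down by the same factor and grossly under-dose at handover
    -- the constrained fit preserves the represented insulin policy.
    """
    if len(samples) == 0:
        raise InvalidInputError("pretraining requires at least one sample")
    x_errs = np.array([s[0] for s in samples], dtype=float)
    us = np.array([s[1] for s in samples], dtype=float)
    b_hat = 1.0 if config.literal_gain_sign else -1.0
    # invert the control law u = (-f_hat - lam*x - d)/b_hat for d
    targets = -b_hat * us - config.f_hat - config.lam * x_errs
    phi_matrix = np.stack([activations(x, network) for x in x_errs])
    weights, *_ = np.linalg.lstsq(phi_matrix, targets, rcond=None)
    norm = float(np.linalg.norm(weights))
    theta = config.theta_bound
    if norm > theta:
        u_svd, s, vt = np.linalg.svd(phi_matrix, full_matrices=False)
        beta = u_svd.T @ targets

        def solution(mu: float) -> np.ndarray:
            return vt.T @ (s / (s * s + mu) * beta)

        lo, hi = 0.0, 1.0
        while float(np.linalg.norm(solution(hi))) > theta:
            hi *= 10.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if float(np.linalg.norm(solution(mid))) > theta:
                lo = mid
            else:
                hi = mid
        weights = solution(hi)
        logger.info(
            "pseudoinverse weight norm %.4g exceeds bound %.4g; "
            "norm-constrained ridge fit applied (mu=%.4g)", norm, theta, hi,
        )
    return RBFNetwork(network.centers.copy(), network.widths.copy(), weights)
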