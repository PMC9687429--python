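"""Identifiable Virtual Patient (IVP) glucose-insulin kinetics.

The virtual patient is a four-state compartment model of subcutaneous
insulin delivery in type 1 diabetes:

.. math::

    \\dot I_{SC} &= -I_{SC}/\\tau_1 + u/(\\tau_1 C_I) \\\\
    \\dot I      &= I_{SC}/\\tau_2 - I/\\tau_2 \\\\
    \\dot I_{EFF}&= -p_2 I_{EFF} + p_2 S_I I \\\\
    \\dot G      &= -(GEZI + I_{EFF})\\,G + EGP + RA(t)

where ``u`` is the subcutaneous insulin infusion rate [uU/min] and
``RA(t)`` is the rate of glucose appearance after meals [mg/dL/min],
modelled as a gamma-like absorption kernel per meal,

.. math::

    RA(t) = \\sum_j \\frac{CH_j\\,(t - t_j)}{V_G \\tau_m^2}
            e^{-(t - t_j)/\\tau_m}, \\qquad t > t_j,

with carbohydrate mass ``CH`` in mg.  Multiple meals superpose linearly
as time-shifted copies of the single-meal kernel.

The module provides the model right-hand side, a classical fixed-step
fourth-order Runge-Kutta integrator, closed-form steady states, and the
sinusoidal intra-patient parameter modulation used to emulate circadian
variability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import IntegrationError, InvalidInputError

logger = logging.getLogger(__name__)

#: Canonical parameter ordering used by :meth:`IVPParameters.as_array`
#: and the fast integration kernels.
PARAM_NAMES: tuple[str, ...] = (
    "tau1", "tau2", "CI", "p2", "SI", "GEZI", "EGP", "tau_m", "VG",
)

STATE_NAMES: tuple[str, ...] = ("I_SC", "I", "I_EFF", "G")


@dataclass(frozen=True)
class IVPParameters:
    """Physiological constants of one virtual patient.

    Defaults are the population mean values used to generate cohorts.

    Units: ``tau1``, ``tau2``, ``tau_m`` [min]; ``CI`` [mL/min];
    ``p2``, ``GEZI`` [1/min]; ``SI`` [mL/uU/min]; ``EGP`` [mg/dL/min];
    ``VG`` [dL].
    """

    tau1: float = 49.0
    tau2: float = 47.0
    CI: float = 2010.0
    p2: float = 1.06e-2
    SI: float = 8.11e-4
    GEZI: float = 2.2e-3
    EGP: float = 1.33
    tau_m: float = 40.5
    VG: float = 253.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise InvalidInputError(
                    f"parameter {name!r} must be strictly positive and "
                    f"finite, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        """Parameters as a float array in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "IVPParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise InvalidInputError(
                f"expected {len(PARAM_NAMES)} parameter values, "
                f"got shape {values.shape}"
            )
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


@dataclass(frozen=True)
class PatientState:
    """One point of the patient trajectory.

    ``I_SC`` and ``I`` are subcutaneous and plasma insulin [uU/mL],
    ``I_EFF`` is the insulin effect on glucose [1/min], ``G`` is blood
    glucose [mg/dL] and ``t`` is simulation time [min].
    """

    I_SC: float
    I: float
    I_EFF: float
    G: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise InvalidInputError(f"state field {name!r} is not finite")
            if value < 0.0:
                raise InvalidInputError(
                    f"state field {name!r} must be non-negative, got {value!r}"
                )
        if not math.isfinite(self.t):
            raise InvalidInputError("time must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.I_SC, self.I, self.I_EFF, self.G], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float], t: float) -> "PatientState":
        return cls(I_SC=float(y[0]), I=float(y[1]), I_EFF=float(y[2]),
                   G=float(y[3]), t=float(t))


@dataclass(frozen=True)
class StateDerivative:
    """Time derivatives of the four patient states (same field order)."""

    I_SC: float
    I: float
    I_EFF: float
    G: float

    def as_array(self) -> np.ndarray:
        return np.array([self.I_SC, self.I, self.I_EFF, self.G], dtype=float)


@dataclass(frozen=True)
class MealEvent:
    """A single carbohydrate intake.

    ``time`` is minutes from simulation start; ``carbs`` is the
    carbohydrate mass in mg.
    """

    time: float
    carbs: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0.0:
            raise InvalidInputError(f"meal time must be >= 0, got {self.time!r}")
        if not math.isfinite(self.carbs) or self.carbs < 0.0:
            raise InvalidInputError(f"meal carbs must be >= 0, got {self.carbs!r}")


@dataclass(frozen=True)
class ParameterModulation:
    """Sinusoidal intra-patient parameter variability.

    Each parameter is scaled as ``p(t) = p_base * (1 + amplitude *
    sin(2*pi*t/period + phase))``, emulating circadian drifts of the
    metabolism.  The default is a +/-10% swing with a one-day period and
    a common zero phase at simulation start (midnight).
    """

    amplitude: float = 0.10
    period: float = 1440.0
    phases: tuple[float, ...] = (0.0,) * len(PARAM_NAMES)

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude < 1.0):
            raise InvalidInputError(
                f"modulation amplitude must be in [0, 1), got {self.amplitude!r}"
            )
        if not (math.isfinite(self.period) and self.period > 0.0):
            raise InvalidInputError(f"modulation period must be > 0, got {self.period!r}")
        if len(self.phases) != len(PARAM_NAMES):
            raise InvalidInputError(
                f"need {len(PARAM_NAMES)} phases, got {len(self.phases)}"
            )

    def phases_array(self) -> np.ndarray:
        return np.asarray(self.phases, dtype=float)


def rate_of_appearance(
    meals: Iterable[MealEvent], t: float, params: IVPParameters
) -> float:
    """Rate of glucose appearance [mg/dL/min] at time ``t``.

    Each past meal contributes ``CH*(t-t_j)/(VG*tau_m^2)*exp(-(t-t_j)/tau_m)``;
    future meals contribute zero, so meal ordering does not matter.  The
    kernel integrates to ``CH/VG`` over all time (total glucose delivered
    per volume of distribution).
    """
    if not math.isfinite(t) or t < 0.0:
        raise InvalidInputError(f"time must be >= 0, got {t!r}")
    vg_tm2 = params.VG * params.tau_m * params.tau_m
    total = 0.0
    for meal in meals:
        dt = t - meal.time
        if dt <= 0.0:
            continue
        total += meal.carbs * dt / vg_tm2 * math.exp(-dt / params.tau_m)
    return total


def _rhs(
    y: tuple[float, float, float, float],
    t: float,
    u: float,
    meals: Sequence[MealEvent],
    p: IVPParameters,
) -> tuple[float, float, float, float]:
    """Model right-hand side on a bare state tuple (hot path helper)."""
    i_sc, i, i_eff, g = y
    ra = rate_of_appearance(meals, t, p)
    return (
        -i_sc / p.tau1 + u / (p.tau1 * p.CI),
        i_sc / p.tau2 - i / p.tau2,
        -p.p2 * i_eff + p.p2 * p.SI * i,
        -(p.GEZI + i_eff) * g + p.EGP + ra,
    )


def derivatives(
    state: PatientState,
    u: float,
    meals: Sequence[MealEvent],
    params: IVPParameters,
) -> StateDerivative:
    """Time derivatives of the four states for infusion ``u`` [uU/min]."""
    if not math.isfinite(u) or u < 0.0:
        raise InvalidInputError(f"infusion rate must be >= 0, got {u!r}")
    k = _rhs((state.I_SC, state.I, state.I_EFF, state.G), state.t, u, meals, params)
    return StateDerivative(*k)


def modulated_parameters(
    base: IVPParameters, t: float, mod: ParameterModulation | None
) -> IVPParameters:
    """Parameters at time ``t`` under sinusoidal modulation.

    Returns ``base`` unchanged when ``mod`` is ``None`` or its amplitude
    is zero.  All outputs stay positive for amplitude < 1.
    """
    if mod is None or mod.amplitude == 0.0:
        return base
    omega = 2.0 * math.pi / mod.period
    values = {}
    for name, phase in zip(PARAM_NAMES, mod.phases):
        values[name] = getattr(base, name) * (1.0 + mod.amplitude * math.sin(omega * t + phase))
    return IVPParameters(**values)


def _rk4_raw(
    y: tuple[float, float, float, float],
    t: float,
    u: float,
    meals: Sequence[MealEvent],
    params: IVPParameters,
    dt: float,
    mod: ParameterModulation | None,
) -> tuple[float, float, float, float]:
    """One classical RK4 step on a bare tuple; parameters are evaluated
    at the three distinct stage times when modulation is active."""
    pa = modulated_parameters(params, t, mod)
    pm = modulated_parameters(params, t + 0.5 * dt, mod)
    pb = modulated_parameters(params, t + dt, mod)
    k1 = _rhs(y, t, u, meals, pa)
    y2 = tuple(y[i] + 0.5 * dt * k1[i] for i in range(4))
    k2 = _rhs(y2, t + 0.5 * dt, u, meals, pm)
    y3 = tuple(y[i] + 0.5 * dt * k2[i] for i in range(4))
    k3 = _rhs(y3, t + 0.5 * dt, u, meals, pm)
    y4 = tuple(y[i] + dt * k3[i] for i in range(4))
    k4 = _rhs(y4, t + dt, u, meals, pb)
    return tuple(
        y[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        for i in range(4)
    )


def rk4_step(
    state: PatientState,
    u: float,
    meals: Sequence[MealEvent],
    params: IVPParameters,
    dt: float,
    modulation: ParameterModulation | None = None,
) -> PatientState:
    """Advance the patient one RK4 step of length ``dt`` [min].

    The infusion ``u`` is held constant over the step (zero-order hold).
    Negative components arising from round-off are clamped to zero with a
    debug log entry; a non-finite result raises :class:`IntegrationError`
    naming the offending field.
    """
    if not (math.isfinite(dt) and dt > 0.0):
        raise InvalidInputError(f"dt must be > 0, got {dt!r}")
    if not math.isfinite(u) or u < 0.0:
        raise InvalidInputError(f"infusion rate must be >= 0, got {u!r}")
    y_new = _rk4_raw(
        (state.I_SC, state.I, state.I_EFF, state.G),
        state.t, u, meals, params, dt, modulation,
    )
    cleaned = []
    for name, value in zip(STATE_NAMES, y_new):
        if not math.isfinite(value):
            raise IntegrationError(
                f"state field {name!r} became non-finite at t={state.t + dt:.6g} min"
            )
        if value < 0.0:
            logger.debug(
                "clamping negative %s=%.3e to 0 at t=%.6g min", name, value, state.t + dt
            )
            value = 0.0
        cleaned.append(value)
    return PatientState.from_array(cleaned, state.t + dt)


def integrate_interval(
    state: PatientState,
    u: float,
    meals: Sequence[MealEvent],
    params: IVPParameters,
    dt: float,
    n_steps: int,
    modulation: ParameterModulation | None = None,
) -> PatientState:
    """Integrate ``n_steps`` RK4 steps with ``u`` held constant.

    Pure-Python reference path; the closed-loop simulator normally uses
    the compiled kernel in :mod:`aidsim.kernels`, which this function
    serves to cross-validate.
    """
    for _ in range(int(n_steps)):
        state = rk4_step(state, u, meals, params, dt, modulation)
    return state


def steady_state(params: IVPParameters, u: float) -> PatientState:
    """Closed-form fixed point of the model under constant infusion ``u``.

    ``I_SC = I = u/CI``, ``I_EFF = SI*u/CI`` and
    ``G = EGP/(GEZI + I_EFF)``.  With ``u = 0`` this is the zero-insulin
    equilibrium ``G = EGP/GEZI``.
    """
    if not math.isfinite(u) or u < 0.0:
        raise InvalidInputError(f"infusion rate must be >= 0, got {u!r}")
    i = u / params.CI
    i_eff = params.SI * i
    g = params.EGP / (params.GEZI + i_eff)
    return PatientState(I_SC=i, I=i, I_EFF=i_eff, G=g, t=0.0)


def basal_for_glucose(params: IVPParameters, g_target: float) -> float:
    """Constant infusion [uU/min] whose steady state has glucose ``g_target``.

    Inverts the fixed-point formulas; only targets below the zero-insulin
    equilibrium ``EGP/GEZI`` are reachable with non-negative infusion.
    """
    if not math.isfinite(g_target) or g_target <= 0.0:
        raise InvalidInputError(f"target glucose must be > 0, got {g_target!r}")
    i_eff = params.EGP / g_target - params.GEZI
    if -1e-9 * params.GEZI < i_eff < 0.0:
        i_eff = 0.0  # round-off at the zero-insulin equilibrium itself
    if i_eff < 0.0:
        raise InvalidInputError(
            f"target glucose {g_target} mg/dL exceeds the zero-insulin "
            f"equilibrium {params.EGP / params.GEZI:.1f} mg/dL"
        )
    return i_eff * params.CI / params.SI
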