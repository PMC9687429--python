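"""Closed-loop coupling of virtual patients and the adaptive controller.

The loop mimics a commercial automated-insulin-delivery setup: blood
glucose is sampled once every 5 minutes (CGM period); at each sample the
controller computes an infusion command which is then held constant
(zero-order hold, standard pump behaviour) while the patient ODE is
integrated at a much finer step; the network weights adapt once per
sample with the learning rate of the current protocol day.

Three study protocols are provided:

``scratch_short``
    The network learns from scratch (``w(0) = 0``) on a cohort of 20
    patients over 7 days, with the tapering learning-rate schedule that
    starts high on day 1.
``hybrid_basal_short``
    Patients first receive 3 days of constant basal therapy (default
    50 U/day) with the adaptive law frozen; the recorded (error,
    infusion) pairs pretrain the network by pseudoinverse, and from day
    4 the adaptive controller takes over with its shifted schedule.
``long_term``
    One patient, 63 days, scratch initialization -- a durability test
    of the learned policy under sustained inter-day variability.

All runs are a pure function of the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import kernels
from .cohort import (
    CohortConfig,
    MealScheduleConfig,
    meal_arrays,
    sample_meal_schedule,
    sample_patient,
)
from .controller import (
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
from .errors import ConfigError, GlucoseExcursionError, IntegrationError
from .patient import (
    STATE_NAMES,
    IVPParameters,
    MealEvent,
    ParameterModulation,
    PatientState,
    basal_for_glucose,
    integrate_interval,
    steady_state,
)

PROTOCOLS = ("scratch_short", "hybrid_basal_short", "long_term")

MINUTES_PER_DAY = 1440.0

#: 50 insulin units per day expressed in uU/min (1 U = 1e6 uU).
DEFAULT_BASAL_RATE = 50.0e6 / MINUTES_PER_DAY


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one in-silico experiment.

    ``n_patients`` and ``days`` default per protocol (20 x 7 for the
    short studies, 1 x 63 for ``long_term``).  ``dt_ode`` is the RK4
    step [min]; ``sample_period`` the CGM/actuation period [min] and
    must be an integer multiple of ``dt_ode``.  ``G0`` is the glycemia
    whose steady state initializes each patient.  ``basal_rate`` and
    ``basal_days`` apply to the hybrid protocol only.
    """

    protocol: str = "scratch_short"
    n_patients: int | None = None
    days: int | None = None
    dt_ode: float = 1.0e-3
    sample_period: float = 5.0
    basal_rate: float = DEFAULT_BASAL_RATE
    basal_days: int = 3
    G0: float = 140.0
    seed: int = 0
    sd_fraction: float = 0.05
    random_phases: bool = False
    glucose_ceiling: float = 1000.0
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    modulation: ParameterModulation = field(default_factory=ParameterModulation)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ConfigError(
                f"unknown protocol {self.protocol!r}; expected one of {PROTOCOLS}")
        if self.n_patients is None:
            object.__setattr__(
                self, "n_patients", 1 if self.protocol == "long_term" else 20)
        if self.days is None:
            object.__setattr__(
                self, "days", 63 if self.protocol == "long_term" else 7)
        if self.days < 1:
            raise ConfigError(f"days must be >= 1, got {self.days!r}")
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients!r}")
        if self.dt_ode <= 0.0 or self.sample_period <= 0.0:
            raise ConfigError("dt_ode and sample_period must be > 0")
        n_sub = round(self.sample_period / self.dt_ode)
        if n_sub < 1 or abs(n_sub * self.dt_ode - self.sample_period) > 1e-9:
            raise ConfigError(
                "sample_period must be a positive integer multiple of dt_ode")
        if self.basal_days < 0:
            raise ConfigError("basal_days must be >= 0")
        if self.basal_rate < 0.0:
            raise ConfigError("basal_rate must be >= 0")
        if self.G0 <= 0.0:
            raise ConfigError("G0 must be > 0")
        if not (0.0 <= self.sd_fraction < 1.0):
            raise ConfigError("sd_fraction must be in [0, 1)")
        if self.glucose_ceiling <= 0.0:
            raise ConfigError("glucose_ceiling must be > 0")

    @property
    def n_substeps(self) -> int:
        return round(self.sample_period / self.dt_ode)

    @property
    def n_samples(self) -> int:
        return round(self.days * MINUTES_PER_DAY / self.sample_period)

    def resolved_eta_schedule(self) -> tuple[tuple[int, float], ...]:
        """Per-protocol default learning schedule unless overridden."""
        if self.controller.eta_schedule is not None:
            return self.controller.eta_schedule
        if self.protocol == "hybrid_basal_short":
            return HYBRID_ETA_SCHEDULE
        return SCRATCH_ETA_SCHEDULE


@dataclass
class SimulationTrace:
    """Sampled closed-loop signals of one patient.

    Arrays are aligned on the 5-min sample grid: glucose and the insulin
    states are the measurements at the start of each control interval,
    ``u`` is the command applied over that interval, ``d_hat`` the
    network output and ``w_norm`` the weight norm when the command was
    computed.  ``RA`` is the meal appearance rate at the sample time.
    """

    t: np.ndarray
    G: np.ndarray
    I_SC: np.ndarray
    I: np.ndarray
    I_EFF: np.ndarray
    u: np.ndarray
    d_hat: np.ndarray
    w_norm: np.ndarray
    RA: np.ndarray
    meals: list[MealEvent]
    params: IVPParameters
    metadata: dict

    def __post_init__(self) -> None:
        n = self.t.shape[0]
        for name in ("G", "I_SC", "I", "I_EFF", "u", "d_hat", "w_norm", "RA"):
            if getattr(self, name).shape[0] != n:
                raise ConfigError(f"trace array {name!r} length mismatch")

    def to_frame(self):
        """Trace as a pandas DataFrame with the canonical column order."""
        import pandas as pd

        return pd.DataFrame({
            "t_min": self.t, "G": self.G, "I_SC": self.I_SC, "I": self.I,
            "I_EFF": self.I_EFF, "u": self.u, "d_hat": self.d_hat,
            "w_norm": self.w_norm, "RA": self.RA,
        })


def _appearance_series(
    t: np.ndarray,
    meal_t: np.ndarray,
    meal_c: np.ndarray,
    vg: np.ndarray,
    tau_m: np.ndarray,
) -> np.ndarray:
    """Vectorized RA(t) over a sample grid with per-time VG and tau_m."""
    if meal_t.size == 0:
        return np.zeros_like(t)
    dt = t[:, None] - meal_t[None, :]
    with np.errstate(over="ignore"):
        kern = dt / (vg * tau_m**2)[:, None] * np.exp(-dt / tau_m[:, None])
    kern[dt <= 0.0] = 0.0
    return kern @ meal_c


def run_patient(
    params: IVPParameters,
    meals: Sequence[MealEvent],
    scenario: ScenarioConfig,
    controller_config: ControllerConfig | None = None,
    *,
    network: RBFNetwork | None = None,
    phases: Sequence[float] | None = None,
    patient_index: int = 0,
    engine: str = "numba",
) -> SimulationTrace:
    """Simulate one patient through the scenario's protocol.

    The patient starts at the steady state matching ``scenario.G0``.
    ``engine`` selects the compiled kernel (default) or the pure-Python
    reference integrator (``"python"``, for validation; much slower).
    """
    if engine not in ("numba", "python"):
        raise ConfigError(f"unknown engine {engine!r}")
    cc = controller_config or scenario.controller
    schedule = scenario.resolved_eta_schedule()
    net = (network or RBFNetwork(
        weights=np.zeros(len(RBFNetwork().centers)))).copy()

    mod = scenario.modulation
    if phases is not None:
        mod = replace(mod, phases=tuple(float(p) for p in phases))
    phases_arr = mod.phases_array()
    common_phase = bool(np.all(phases_arr == phases_arr[0]))
    omega = 2.0 * math.pi / mod.period

    dt = scenario.dt_ode
    n_sub = scenario.n_substeps
    n_samples = scenario.n_samples
    sp = scenario.sample_period

    u0 = basal_for_glucose(params, scenario.G0)
    st0 = steady_state(params, u0)
    y = st0.as_array()
    base = params.as_array()
    meal_t, meal_c = meal_arrays(meals)

    hybrid = scenario.protocol == "hybrid_basal_short"
    basal_until = scenario.basal_days * MINUTES_PER_DAY if hybrid else 0.0
    pretrained = not hybrid
    basal_records: list[tuple[float, float]] = []

    cols = {name: np.empty(n_samples) for name in
            ("t", "G", "I_SC", "I", "I_EFF", "u", "d_hat", "w_norm")}

    for k in range(n_samples):
        t = k * sp
        g = y[3]
        if g > scenario.glucose_ceiling:
            raise GlucoseExcursionError(
                f"patient {patient_index}: G = {g:.1f} mg/dL exceeded the "
                f"{scenario.glucose_ceiling:.0f} mg/dL ceiling at t = {t:.0f} min")
        in_basal = hybrid and t < basal_until
        if not in_basal and not pretrained:
            net = pretrain_from_basal(basal_records, net, cc)
            pretrained = True
        x_err = g - cc.x_d
        d_hat = disturbance_estimate(x_err, net)
        if in_basal:
            u = scenario.basal_rate
            basal_records.append((x_err, u))
        else:
            u = control_action(x_err, d_hat, cc)

        cols["t"][k] = t
        cols["G"][k] = g
        cols["I_SC"][k] = y[0]
        cols["I"][k] = y[1]
        cols["I_EFF"][k] = y[2]
        cols["u"][k] = u
        cols["d_hat"][k] = d_hat
        cols["w_norm"][k] = net.weight_norm

        if engine == "numba":
            status = kernels.integrate_span(
                y, t, u, n_sub, dt, base,
                mod.amplitude, omega, phases_arr, common_phase,
                meal_t, meal_c,
            )
            if status != kernels.STATUS_OK:
                name = STATE_NAMES[status - kernels.STATUS_NONFINITE_BASE]
                raise IntegrationError(
                    f"patient {patient_index}: state field {name!r} became "
                    f"non-finite near t = {t:.0f} min")
        else:
            try:
                state = integrate_interval(
                    PatientState.from_array(y, t), u, meals, params,
                    dt, n_sub, mod)
            except IntegrationError as exc:
                raise IntegrationError(
                    f"patient {patient_index} near t = {t:.0f} min: {exc}"
                ) from exc
            y = state.as_array()

        if not in_basal:
            day = int(t // MINUTES_PER_DAY) + 1
            eta = learning_rate(day, schedule)
            if eta != 0.0:
                net = update_weights(net, x_err, eta, sp, cc.theta_bound)

    vg_t = params.VG * (1.0 + mod.amplitude * np.sin(omega * cols["t"] + phases_arr[8]))
    taum_t = params.tau_m * (1.0 + mod.amplitude * np.sin(omega * cols["t"] + phases_arr[7]))
    ra = _appearance_series(cols["t"], meal_t, meal_c, vg_t, taum_t)

    metadata = {
        "protocol": scenario.protocol,
        "patient_index": patient_index,
        "seed": scenario.seed,
        "G0": scenario.G0,
        "dt_ode": scenario.dt_ode,
        "sample_period": scenario.sample_period,
        "modulation_amplitude": mod.amplitude,
        "modulation_period": mod.period,
        "modulation_phases": list(mod.phases),
        "eta_schedule": [list(pair) for pair in schedule],
        "x_d": cc.x_d,
        "lam": cc.lam,
        "theta_bound": cc.theta_bound,
        "engine": engine,
        "final_weights": net.weights.tolist(),
    }
    if hybrid:
        metadata["basal_rate"] = scenario.basal_rate
        metadata["basal_days"] = scenario.basal_days
    return SimulationTrace(
        t=cols["t"], G=cols["G"], I_SC=cols["I_SC"], I=cols["I"],
        I_EFF=cols["I_EFF"], u=cols["u"], d_hat=cols["d_hat"],
        w_norm=cols["w_norm"], RA=ra,
        meals=list(meals), params=params, metadata=metadata,
    )


def build_cohort(
    scenario: ScenarioConfig,
) -> list[tuple[IVPParameters, list[MealEvent], tuple[float, ...] | None]]:
    """Sample patients, meal schedules and (optionally) modulation phases.

    Sub-seeds are derived from the scenario seed with distinct tags so
    that parameters, meals and phases are independent streams.
    """
    cohort_cfg = CohortConfig(
        n_patients=scenario.n_patients,
        sd_fraction=scenario.sd_fraction,
        seed=(scenario.seed, 0),
    )
    out = []
    for i in range(scenario.n_patients):
        p = sample_patient(cohort_cfg, i)
        meals = sample_meal_schedule(
            MealScheduleConfig(days=scenario.days, seed=(scenario.seed, 1, i)))
        phases = None
        if scenario.random_phases:
            rng = np.random.default_rng(
                np.random.SeedSequence([scenario.seed, 2, i]))
            phases = tuple(rng.uniform(0.0, 2.0 * math.pi, 9).tolist())
        out.append((p, meals, phases))
    return out


def run_scenario(
    scenario: ScenarioConfig, *, engine: str = "numba"
) -> list[SimulationTrace]:
    """Run the full protocol for every patient in the cohort."""
    traces = []
    for i, (params, meals, phases) in enumerate(build_cohort(scenario)):
        traces.append(run_patient(
            params, meals, scenario,
            phases=phases, patient_index=i, engine=engine,
        ))
    return traces


def analysis_window(trace: SimulationTrace, start_day: int = 3) -> np.ndarray:
    """Boolean mask of samples at or after the start of ``start_day + 1``.

    The default drops the first three days: the scratch learning phase
    in the scratch/long-term protocols, or the basal-therapy phase in
    the hybrid protocol.
    """
    return trace.t >= start_day * MINUTES_PER_DAY
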