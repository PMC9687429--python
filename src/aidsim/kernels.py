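"""Compiled fixed-step integration kernel for the virtual patient ODE.

The closed-loop simulator integrates the four-state model over each
5-min control interval at a fine step (default 1e-3 min), which amounts
to hundreds of millions of RK4 stages per cohort study.  This module
holds a numba-compiled kernel for that inner loop.  It mirrors, stage
for stage, the pure-Python reference in :mod:`aidsim.patient`
(``integrate_interval``), which the test suite uses to cross-validate it.

Conventions shared with the reference path:

* parameters are modulated at the three distinct RK4 stage times
  ``t``, ``t + dt/2`` and ``t + dt``;
* negative state components (round-off artifacts) are clamped to zero
  after each full step;
* meals must be sorted by time; contributions older than 60 absorption
  time constants (below double precision relative to the kernel peak)
  are skipped so that long schedules stay O(active meals) per stage.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: status codes returned by :func:`integrate_span`
STATUS_OK = 0
#: non-finite state; code = 1 + index of the offending field
STATUS_NONFINITE_BASE = 1


@njit(cache=True)
def _fill_params(out, base, t, amp, omega, phases, common_phase):
    if amp == 0.0:
        for j in range(9):
            out[j] = base[j]
    elif common_phase:
        f = 1.0 + amp * np.sin(omega * t + phases[0])
        for j in range(9):
            out[j] = base[j] * f
    else:
        for j in range(9):
            out[j] = base[j] * (1.0 + amp * np.sin(omega * t + phases[j]))


@njit(cache=True)
def _ra(t, vg, tau_m, meal_t, meal_c, lo, hi):
    total = 0.0
    denom = vg * tau_m * tau_m
    for i in range(lo, hi):
        dt = t - meal_t[i]
        if dt <= 0.0:
            continue
        if dt > 60.0 * tau_m:
            continue
        total += meal_c[i] * dt / denom * np.exp(-dt / tau_m)
    return total


@njit(cache=True)
def _deriv(i_sc, i, i_eff, g, u, p, ra):
    d_isc = -i_sc / p[0] + u / (p[0] * p[2])
    d_i = i_sc / p[1] - i / p[1]
    d_ieff = -p[3] * i_eff + p[3] * p[4] * i
    d_g = -(p[5] + i_eff) * g + p[6] + ra
    return d_isc, d_i, d_ieff, d_g


@njit(cache=True)
def integrate_span(
    y, t0, u, n_steps, dt,
    base, amp, omega, phases, common_phase,
    meal_t, meal_c,
):
    """Advance state ``y`` (modified in place) by ``n_steps`` RK4 steps.

    ``y`` is the 4-vector (I_SC, I, I_EFF, G); ``base`` the 9 model
    parameters in canonical order; ``omega = 2*pi/period`` of the
    sinusoidal modulation with fractional ``amp`` and per-parameter
    ``phases``.  Returns a status code (0 = ok, 1..4 = field 1..4 went
    non-finite).
    """
    n_meals = meal_t.shape[0]
    lo = 0
    hi = 0
    pa = np.empty(9)
    pm = np.empty(9)
    pb = np.empty(9)
    i_sc = y[0]
    i = y[1]
    i_eff = y[2]
    g = y[3]
    for k in range(n_steps):
        t = t0 + k * dt
        t_end = t + dt
        while hi < n_meals and meal_t[hi] <= t_end:
            hi += 1
        while lo < hi and t - meal_t[lo] > 4000.0:
            lo += 1
        t_mid = t + 0.5 * dt
        _fill_params(pa, base, t, amp, omega, phases, common_phase)
        _fill_params(pm, base, t_mid, amp, omega, phases, common_phase)
        _fill_params(pb, base, t_end, amp, omega, phases, common_phase)
        ra_a = _ra(t, pa[8], pa[7], meal_t, meal_c, lo, hi)
        ra_m = _ra(t_mid, pm[8], pm[7], meal_t, meal_c, lo, hi)
        ra_b = _ra(t_end, pb[8], pb[7], meal_t, meal_c, lo, hi)

        k1 = _deriv(i_sc, i, i_eff, g, u, pa, ra_a)
        k2 = _deriv(
            i_sc + 0.5 * dt * k1[0], i + 0.5 * dt * k1[1],
            i_eff + 0.5 * dt * k1[2], g + 0.5 * dt * k1[3],
            u, pm, ra_m,
        )
        k3 = _deriv(
            i_sc + 0.5 * dt * k2[0], i + 0.5 * dt * k2[1],
            i_eff + 0.5 * dt * k2[2], g + 0.5 * dt * k2[3],
            u, pm, ra_m,
        )
        k4 = _deriv(
            i_sc + dt * k3[0], i + dt * k3[1],
            i_eff + dt * k3[2], g + dt * k3[3],
            u, pb, ra_b,
        )
        i_sc = i_sc + dt / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
        i = i + dt / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
        i_eff = i_eff + dt / 6.0 * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
        g = g + dt / 6.0 * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3])

        if not (np.isfinite(i_sc) and np.isfinite(i)
                and np.isfinite(i_eff) and np.isfinite(g)):
            y[0] = i_sc
            y[1] = i
            y[2] = i_eff
            y[3] = g
            if not np.isfinite(i_sc):
                return STATUS_NONFINITE_BASE + 0
            if not np.isfinite(i):
                return STATUS_NONFINITE_BASE + 1
            if not np.isfinite(i_eff):
                return STATUS_NONFINITE_BASE + 2
            return STATUS_NONFINITE_BASE + 3
        if i_sc < 0.0:
            i_sc = 0.0
        if i < 0.0:
            i = 0.0
        if i_eff < 0.0:
            i_eff = 0.0
        if g < 0.0:
            g = 0.0
    y[0] = i_sc
    y[1] = i
    y[2] = i_eff
    y[3] = g
    return STATUS_OK
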