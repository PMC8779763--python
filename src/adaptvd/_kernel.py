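"""Compiled fixed-step RK4 integrator for the linear time-varying system.

State layout: ``(A1, A2, A3, E)`` — amounts (mg/kg body weight) in the
serum, tissue and peripheral compartments plus a cumulative-elimination
accumulator, so mass balance can be checked to machine precision.

The right-hand side is

    dA1/dt = -(K(t) + K12 + K13)*A1 + K21(t)*A2 + K31*A3
    dA2/dt =  K12*A1 - K21(t)*A2
    dA3/dt =  K13*A1 - K31*A3
    dE/dt  =  K(t)*A1

with ``K21(t) = K21/f(t)`` and ``K(t) = K/f(t)`` under the default
scaling convention (identity when the corresponding flag is 0).
Expansion kinds are dispatched on an integer code, matching
``adaptvd.expansion.KIND_CODES``.
"""

import math

import numpy as np
from numba import njit

__all__ = ["integrate_mesh"]


@njit(cache=True, inline="always")
def _fval(kind, p1, p2, p3, t):
    if kind == 0:  # constant
        return 1.0
    if kind == 1:  # linear: X = p1
        return 1.0 + p1 * t
    if kind == 2:  # hill_exp: emax, t50, hill
        if t <= 0.0:
            return 1.0
        th = t ** p3
        return math.exp(p1 * th / (p2 ** p3 + th))
    if kind == 3:  # logistic: m1, m2, m3
        L0 = 1.0 / (1.0 + math.exp(p2 * p3))
        if L0 >= 1.0:
            return 1.0
        L = 1.0 / (1.0 + math.exp(-p2 * (t - p3)))
        return 1.0 + (p1 - 1.0) * (L - L0) / (1.0 - L0)
    # sqrt_sigmoid: b1, b2, b3
    S0 = 0.5 * (1.0 + (-p2) / math.sqrt(p2 * p2 + p3))
    u = t - p2
    S = 0.5 * (1.0 + u / math.sqrt(u * u + p3))
    return 1.0 + (p1 - 1.0) * (S - S0) / (1.0 - S0)


@njit(cache=True, inline="always")
def _deriv(t, a1, a2, a3, kind, p1, p2, p3, k, k12, k21, k13, k31,
           sc_k, sc_k21):
    f = _fval(kind, p1, p2, p3, t)
    kt = k / f if sc_k else k
    k21t = k21 / f if sc_k21 else k21
    d1 = -(kt + k12 + k13) * a1 + k21t * a2 + k31 * a3
    d2 = k12 * a1 - k21t * a2
    d3 = k13 * a1 - k31 * a3
    de = kt * a1
    return d1, d2, d3, de


@njit(cache=True)
def integrate_mesh(mesh, bolus, rec, kind, p1, p2, p3,
                   k, k12, k21, k13, k31, sc_k, sc_k21, dt_max, out):
    """March the state across ``mesh`` (sorted times starting at 0).

    At mesh point *i* the state is first recorded into ``out[rec[i]]``
    (if ``rec[i] >= 0``) and the bolus ``bolus[i]`` is then added to A1 —
    i.e. an observation coinciding with a dose time reads the trough.
    Intervals are subdivided into RK4 steps of at most ``dt_max`` days.
    Returns 0 on success, 1 if the state went non-finite.
    """
    a1 = 0.0
    a2 = 0.0
    a3 = 0.0
    e = 0.0
    for i in range(mesh.shape[0]):
        if i > 0:
            t0 = mesh[i - 1]
            t1 = mesh[i]
            span = t1 - t0
            if span > 0.0:
                nsub = int(math.ceil(span / dt_max))
                if nsub < 1:
                    nsub = 1
                h = span / nsub
                for s in range(nsub):
                    ts = t0 + s * h
                    k1a, k1b, k1c, k1e = _deriv(
                        ts, a1, a2, a3, kind, p1, p2, p3,
                        k, k12, k21, k13, k31, sc_k, sc_k21)
                    k2a, k2b, k2c, k2e = _deriv(
                        ts + 0.5 * h, a1 + 0.5 * h * k1a, a2 + 0.5 * h * k1b,
                        a3 + 0.5 * h * k1c, kind, p1, p2, p3,
                        k, k12, k21, k13, k31, sc_k, sc_k21)
                    k3a, k3b, k3c, k3e = _deriv(
                        ts + 0.5 * h, a1 + 0.5 * h * k2a, a2 + 0.5 * h * k2b,
                        a3 + 0.5 * h * k2c, kind, p1, p2, p3,
                        k, k12, k21, k13, k31, sc_k, sc_k21)
                    k4a, k4b, k4c, k4e = _deriv(
                        ts + h, a1 + h * k3a, a2 + h * k3b,
                        a3 + h * k3c, kind, p1, p2, p3,
                        k, k12, k21, k13, k31, sc_k, sc_k21)
                    a1 += h / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
                    a2 += h / 6.0 * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
                    a3 += h / 6.0 * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)
                    e += h / 6.0 * (k1e + 2.0 * k2e + 2.0 * k3e + k4e)
        if not (math.isfinite(a1) and math.isfinite(a2)
                and math.isfinite(a3) and math.isfinite(e)):
            return 1
        r = rec[i]
        if r >= 0:
            out[r, 0] = a1
            out[r, 1] = a2
            out[r, 2] = a3
            out[r, 3] = e
        a1 += bolus[i]
    return 0
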