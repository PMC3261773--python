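"""Full lactotroph model: currents, activation curves, right-hand side.

The model has one fast variable, the membrane potential ``V`` (mV), and two
slower variables: ``n``, the delayed-rectifier K+ activation, and ``c``, the
cytosolic free Ca2+ concentration (uM).

    Cm dV/dt = -(I_Ca + I_K + I_KCa + I_BK)
       dn/dt = (n_inf(V) - n) / tau_n
       dc/dt = -fc (alpha I_Ca + kc c)

All functions accept numpy arrays and broadcast.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams

__all__ = [
    "boltzmann", "boltzmann_d1", "boltzmann_d2", "hill2", "hill2_d1",
    "hill2_d2", "activation", "currents", "rhs_full", "rhs_ode",
    "jacobian_full", "time_constants",
]

# Clamp for exponential arguments: far outside the physiological voltage
# range the Boltzmann functions saturate exactly, so clamping changes nothing
# measurable while preventing overflow.
_EXP_CLAMP = 500.0


def _exp(x):
    return np.exp(np.clip(x, -_EXP_CLAMP, _EXP_CLAMP))


def boltzmann(V, v_half, s):
    """Sigmoidal steady-state activation 1 / (1 + exp((v_half - V)/s))."""
    return 1.0 / (1.0 + _exp((v_half - V) / s))


def boltzmann_d1(V, v_half, s):
    m = boltzmann(V, v_half, s)
    return m * (1.0 - m) / s


def boltzmann_d2(V, v_half, s):
    m = boltzmann(V, v_half, s)
    return m * (1.0 - m) * (1.0 - 2.0 * m) / (s * s)


def hill2(c, Kd):
    """Hill activation with exponent 2: c^2 / (c^2 + Kd^2)."""
    c2 = c * c
    return c2 / (c2 + Kd * Kd)


def hill2_d1(c, Kd):
    k2 = Kd * Kd
    den = c * c + k2
    return 2.0 * c * k2 / (den * den)


def hill2_d2(c, Kd):
    k2 = Kd * Kd
    den = c * c + k2
    return 2.0 * k2 * (k2 - 3.0 * c * c) / (den * den * den)


def activation(x, which: str, p: ModelParams):
    """Steady-state activation value for channel ``which`` in {m, n, b, s}.

    ``m``, ``n``, ``b`` are Boltzmann functions of voltage; ``s`` is a Hill
    function (exponent 2, half-max at Kd) of the Ca2+ concentration.
    """
    if which == "m":
        return boltzmann(x, p.vm, p.sm)
    if which == "n":
        return boltzmann(x, p.vn, p.sn)
    if which == "b":
        return boltzmann(x, p.vb, p.sb)
    if which == "s":
        return hill2(x, p.Kd)
    raise ValueError(f"unknown activation {which!r}")


def currents(V, n, c, p: ModelParams):
    """Ionic currents (I_Ca, I_K, I_KCa, I_BK) in pA.

    I_Ca is inward (negative) for V < V_Ca; the K+ currents are outward
    (positive) for V > V_K.
    """
    ICa = p.gCa * boltzmann(V, p.vm, p.sm) * (V - p.VCa)
    IK = p.gK * n * (V - p.VK)
    IKCa = p.gKCa * hill2(c, p.Kd) * (V - p.VK)
    IBK = p.gBK * boltzmann(V, p.vb, p.sb) * (V - p.VK)
    return ICa, IK, IKCa, IBK


def rhs_full(state, p: ModelParams):
    """Time derivatives (dV/dt, dn/dt, dc/dt) of the full model."""
    if p.Cm <= 0:
        raise ValueError("Cm must be > 0")
    V, n, c = state
    ICa, IK, IKCa, IBK = currents(V, n, c, p)
    f = -(ICa + IK + IKCa + IBK)
    dV = f / p.Cm
    dn = (boltzmann(V, p.vn, p.sn) - n) / p.taun
    dc = -p.fc * (p.alpha * ICa + p.kc * c)
    return np.array([dV, dn, dc])


def rhs_ode(t, y, p: ModelParams):
    """solve_ivp-compatible wrapper around :func:`rhs_full`."""
    return rhs_full(y, p)


def jacobian_full(state, p: ModelParams):
    """Analytic 3x3 Jacobian of :func:`rhs_full` at ``state``.

    The c-row depends only on (V, c): the Ca2+ balance contains no n term.
    """
    V, n, c = state
    m = boltzmann(V, p.vm, p.sm)
    dm = boltzmann_d1(V, p.vm, p.sm)
    b = boltzmann(V, p.vb, p.sb)
    db = boltzmann_d1(V, p.vb, p.sb)
    s = hill2(c, p.Kd)
    ds = hill2_d1(c, p.Kd)

    dICa_dV = p.gCa * (dm * (V - p.VCa) + m)
    dIBK_dV = p.gBK * (db * (V - p.VK) + b)
    # partials of f = -(sum of currents), at fixed (V, n, c)
    fV = -(dICa_dV + p.gK * n + p.gKCa * s + dIBK_dV)
    fn = -p.gK * (V - p.VK)
    fc_ = -p.gKCa * ds * (V - p.VK)

    dninf = boltzmann_d1(V, p.vn, p.sn)
    return np.array([
        [fV / p.Cm, fn / p.Cm, fc_ / p.Cm],
        [dninf / p.taun, -1.0 / p.taun, 0.0],
        [-p.fc * p.alpha * dICa_dV, 0.0, -p.fc * p.kc],
    ])


def g_total(V, n, c, p: ModelParams):
    """Total membrane conductance (nS) entering the voltage time constant."""
    return (
        p.gK * n
        + p.gBK * boltzmann(V, p.vb, p.sb)
        + p.gCa * boltzmann(V, p.vm, p.sm)
        + p.gKCa * hill2(c, p.Kd)
    )


def time_constants(p: ModelParams, trace=None):
    """Characteristic time scales of the three variables.

    Returns ``(tauV_range, tau_n, tau_c)`` in ms, where ``tauV_range`` is the
    (min, max) of Cm/g_total along a supplied trace of (V, n, c) arrays, or
    ``None`` when no trace is given.  ``tau_c = 1/(fc kc)`` depends on neither
    g_K nor g_BK.
    """
    tau_c = 1.0 / (p.fc * p.kc)
    tauV = None
    if trace is not None:
        V, n, c = trace
        V = np.asarray(V)
        if V.size == 0:
            raise ValueError("empty trace")
        g = g_total(V, np.asarray(n), np.asarray(c), p)
        tauV = (p.Cm / np.max(g), p.Cm / np.min(g))
    return tauV, p.taun, tau_c
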