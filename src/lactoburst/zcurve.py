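"""Two-fast/one-slow comparison analysis: the fast-subsystem z-curve.

Treating c as a frozen parameter, the (V, n) fast subsystem has equilibria
f(V, c, n_inf(V)) = 0 which trace out a z-shaped branch diagram over c
("z-curve").  Limit points are c values where the equilibrium count changes;
Hopf points are crossings of the complex eigenvalue pair of the 2x2 fast
Jacobian.  The full-system equilibria are the intersections of the z-curve
with the c-nullcline alpha I_Ca + kc c = 0.

For the lactotroph this decomposition explains less than the
one-fast/two-slow analysis: the pseudo-plateau burst trajectory only weakly
follows the z-curve, and the spiking/bursting transition is not visible in
it.  The module exists to make that comparison reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import boltzmann, boltzmann_d1
from .manifold import V_SCAN_RANGE, f_and_partials
from .params import ModelParams

__all__ = ["ZCurve", "fast_equilibria", "build_zcurve", "hopf_criticality"]


def fast_equilibria(c: float, p: ModelParams):
    """All fast-subsystem equilibria at frozen c: (V, n, stability) tuples.

    stability is 'stable' / 'unstable' / 'saddle' from the 2x2 Jacobian.
    """
    def h(V):
        return f_and_partials(V, c, boltzmann(V, p.vn, p.sn), p)[0]

    grid = np.linspace(*V_SCAN_RANGE, 2001)
    vals = h(grid)
    sign = np.sign(vals)
    out = []
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        V = brentq(h, grid[i], grid[i + 1], xtol=1e-12)
        n = float(boltzmann(V, p.vn, p.sn))
        J = _jac_at(V, n, c, p)
        eig = np.linalg.eigvals(J)
        if np.all(np.abs(eig.imag) < 1e-12) and eig.real[0] * eig.real[1] < 0:
            stab = "saddle"
        else:
            stab = "stable" if np.max(eig.real) < 0 else "unstable"
        out.append((float(V), n, stab))
    return out


def _jac_at(V, n, c, p: ModelParams):
    _, fV, _, fn = f_and_partials(V, c, n, p)
    return np.array([[fV / p.Cm, fn / p.Cm],
                     [boltzmann_d1(V, p.vn, p.sn) / p.taun, -1.0 / p.taun]])


def _max_re(V, n, c, p):
    return float(np.max(np.linalg.eigvals(_jac_at(V, n, c, p)).real))


@dataclass
class ZCurve:
    samples: pd.DataFrame                       # c, V, n, stability
    limit_points: list[tuple[float, float]] = field(default_factory=list)
    hopf_points: list[tuple[float, float]] = field(default_factory=list)


def build_zcurve(p: ModelParams, c_range=(0.0, 1.4), n_c: int = 561) -> ZCurve:
    """Sweep c, collect fast equilibria, and bisect for limit and Hopf points."""
    rows = []
    counts = []
    c_grid = np.linspace(*c_range, n_c)
    for c in c_grid:
        eqs = fast_equilibria(c, p)
        counts.append(len(eqs))
        for V, n, stab in eqs:
            rows.append({"c": float(c), "V": V, "n": n, "stability": stab})
    df = pd.DataFrame(rows)

    limit_points = []
    for i in np.nonzero(np.diff(counts) != 0)[0]:
        lo, hi = c_grid[i], c_grid[i + 1]
        n_lo = counts[i]
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if len(fast_equilibria(mid, p)) == n_lo:
                lo = mid
            else:
                hi = mid
        eqs_lo = {round(V, 3) for V, _, _ in fast_equilibria(lo, p)}
        eqs_hi = {round(V, 3) for V, _, _ in fast_equilibria(hi, p)}
        changed = eqs_lo.symmetric_difference(eqs_hi)
        V_lp = float(np.mean(sorted(changed))) if changed else np.nan
        limit_points.append((0.5 * (lo + hi), V_lp))

    # Hopf points: track each branch (matched by V proximity) for a sign
    # change of the leading real part among complex pairs
    hopf_points = []
    prev = fast_equilibria(c_grid[0], p)
    prev_c = c_grid[0]
    for c in c_grid[1:]:
        cur = fast_equilibria(c, p)
        for V, n, _ in cur:
            match = min(prev, key=lambda e: abs(e[0] - V)) if prev else None
            if match is None or abs(match[0] - V) > 5.0:
                continue
            r0 = _branch_hopf_test(match[0], prev_c, p)
            r1 = _branch_hopf_test(V, c, p)
            if np.isfinite(r0) and np.isfinite(r1) and r0 * r1 < 0:
                c_h = brentq(lambda cc: _branch_hopf_test(
                    _follow_V(cc, V, p), cc, p), prev_c, c, xtol=1e-10)
                V_h = _follow_V(c_h, V, p)
                if not any(abs(c_h - ch) < 1e-6 for ch, _ in hopf_points):
                    hopf_points.append((float(c_h), float(V_h)))
        prev, prev_c = cur, c
    return ZCurve(df, limit_points, hopf_points)


def _follow_V(c, V_guess, p):
    """The fast equilibrium V nearest a guess at frozen c."""
    eqs = fast_equilibria(c, p)
    return min(eqs, key=lambda e: abs(e[0] - V_guess))[0]


def _branch_hopf_test(V, c, p):
    """Real part of the complex pair of the fast Jacobian; NaN if real."""
    n = float(boltzmann(V, p.vn, p.sn))
    eig = np.linalg.eigvals(_jac_at(V, n, c, p))
    if np.max(np.abs(eig.imag)) < 1e-12:
        return np.nan
    return float(np.max(eig.real))


def hopf_criticality(c_hopf: float, V_hopf: float, p: ModelParams,
                     offset: float = 1e-3, t_end: float = 5000.0) -> str:
    """Probe sub/supercriticality of a fast-subsystem Hopf by simulation.

    Integrates the (V, n) fast subsystem from a tiny perturbation of the
    equilibrium just on the unstable side of the Hopf: growth that saturates
    in a small limit cycle implies supercritical; escape to a distant
    attractor implies subcritical (no stable cycle was born).
    """
    for dc in (+5e-3, -5e-3):
        c = c_hopf + dc
        V = _follow_V(c, V_hopf, p)
        n = float(boltzmann(V, p.vn, p.sn))
        if _max_re(V, n, c, p) > 0:
            break
    else:
        return "undetermined"

    def rhs(t, y):
        f = f_and_partials(y[0], c, y[1], p)[0]
        return (f / p.Cm,
                (boltzmann(y[0], p.vn, p.sn) - y[1]) / p.taun)

    y0 = (V + offset, n)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                    rtol=1e-8, atol=1e-10)
    tail = sol.y[0, sol.t > 0.5 * t_end]
    dev = float(np.max(np.abs(tail - V)))
    return "subcritical" if dev > 10.0 else "supercritical"
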