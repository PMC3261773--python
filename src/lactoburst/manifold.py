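"""Critical manifold of the one-fast/two-slow decomposition.

In the singular limit Cm -> 0, trajectories collapse onto the critical
manifold S = {f(V, c, n) = 0}, where f is the total ionic current entering
the voltage equation.  S is a folded surface with attracting lower/upper
sheets (df/dV < 0) and a repelling middle sheet (df/dV > 0), separated by
two fold curves L- and L+ along which df/dV = 0.

Because f is linear in the lumped conductance g_K n + g_KCa s_inf(c), the
fold condition reduces to a scalar equation in V alone,

    phi(V) = (A'(V) + B'(V)) (V - V_K) - (A(V) + B(V)) = 0,

with A = g_Ca m_inf (V - V_Ca) and B = g_BK b_inf (V - V_K): the folds are
two constant-voltage levels V- < V+, independent of c and of g_K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .model import (
    boltzmann, boltzmann_d1, boltzmann_d2, hill2, hill2_d1,
)
from .params import ModelParams

__all__ = [
    "f_and_partials", "n_of", "phi", "phi_d1", "fold_voltages",
    "n_on_fold", "project_to_sheet", "fold_curves", "FoldCurves",
    "ProjectionError", "V_SCAN_RANGE",
]

# Voltage window scanned for folds, equilibria and projections (mV); spans
# the physiological range between the K+ and Ca2+ reversal potentials.
V_SCAN_RANGE = (-75.0, 50.0)


class ProjectionError(RuntimeError):
    """No root of f on the requested sheet (orbit left the fold regime)."""


def _AB(V, p: ModelParams):
    """A(V) = I_Ca and B(V) = I_BK with their first two V-derivatives."""
    m = boltzmann(V, p.vm, p.sm)
    dm = boltzmann_d1(V, p.vm, p.sm)
    d2m = boltzmann_d2(V, p.vm, p.sm)
    b = boltzmann(V, p.vb, p.sb)
    db = boltzmann_d1(V, p.vb, p.sb)
    d2b = boltzmann_d2(V, p.vb, p.sb)
    A = p.gCa * m * (V - p.VCa)
    dA = p.gCa * (dm * (V - p.VCa) + m)
    d2A = p.gCa * (d2m * (V - p.VCa) + 2.0 * dm)
    B = p.gBK * b * (V - p.VK)
    dB = p.gBK * (db * (V - p.VK) + b)
    d2B = p.gBK * (d2b * (V - p.VK) + 2.0 * db)
    return A, dA, d2A, B, dB, d2B


def f_and_partials(V, c, n, p: ModelParams):
    """f(V, c, n) and its partials (f, df/dV, df/dc, df/dn) at fixed state."""
    A, dA, _, B, dB, _ = _AB(V, p)
    s = hill2(c, p.Kd)
    f = -(A + B + (p.gK * n + p.gKCa * s) * (V - p.VK))
    fV = -(dA + dB + p.gK * n + p.gKCa * s)
    fc = -p.gKCa * hill2_d1(c, p.Kd) * (V - p.VK)
    fn = -p.gK * (V - p.VK)
    return f, fV, fc, fn


def n_of(c, V, p: ModelParams):
    """n on the critical manifold: the explicit solution of f = 0 for n."""
    if p.gK <= 0:
        raise ValueError("n_of requires gK > 0")
    if np.any(np.asarray(V) == p.VK):
        raise ValueError("n_of is singular at V = VK")
    m = boltzmann(V, p.vm, p.sm)
    b = boltzmann(V, p.vb, p.sb)
    s = hill2(c, p.Kd)
    return -(p.gCa * m * (V - p.VCa) / (V - p.VK) + p.gKCa * s + p.gBK * b) / p.gK


def phi(V, p: ModelParams):
    """Scalar fold-voltage function; folds are the roots of phi."""
    A, dA, _, B, dB, _ = _AB(V, p)
    return (dA + dB) * (V - p.VK) - (A + B)


def phi_d1(V, p: ModelParams):
    """d phi/dV = (A'' + B'')(V - V_K)."""
    _, _, d2A, _, _, d2B = _AB(V, p)
    return (d2A + d2B) * (V - p.VK)


def _scan_roots(fun: Callable[[float], float], lo: float, hi: float,
                n_grid: int = 2001, xtol: float = 1e-10) -> list[float]:
    """All simple roots of a scalar function by dense sign-scan + bisection."""
    x = np.linspace(lo, hi, n_grid)
    y = np.asarray([fun(xi) for xi in x]) if not _vectorizable(fun, x) else fun(x)
    y = np.asarray(y, dtype=float)
    roots = []
    sign = np.sign(y)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(brentq(fun, x[i], x[i + 1], xtol=xtol))
    for i in np.nonzero(y == 0.0)[0]:
        roots.append(float(x[i]))
    return sorted(roots)


def _vectorizable(fun, x) -> bool:
    try:
        out = fun(x[:2])
        return np.shape(out) == (2,)
    except Exception:
        return False


def fold_voltages(p: ModelParams, n_grid: int = 2001):
    """The two fold voltage levels (V-, V+), or None if the folds are gone.

    The folds merge and vanish at large g_BK; their absence is a valid state
    (the manifold is then a simple sheet).  The values depend on g_Ca, g_BK
    and the activation-curve shapes but on neither g_K nor c.
    """
    roots = _scan_roots(lambda V: phi(V, p), *V_SCAN_RANGE, n_grid=n_grid)
    if len(roots) < 2:
        return None
    if len(roots) > 2:  # keep the pair bracketing the repelling branch
        roots = roots[:2]
    return roots[0], roots[1]


def n_on_fold(c, V_fold: float, p: ModelParams):
    """n-parameterization n(c) of a fold curve at fold level ``V_fold``.

    On the fold both f = 0 and df/dV = 0 pin the same lumped conductance, so
    this coincides with :func:`n_of` evaluated at the fold voltage.
    """
    return n_of(c, V_fold, p)


def project_to_sheet(c, n, target: str, p: ModelParams,
                     folds: tuple[float, float] | None = None) -> float:
    """Project (c, n) along the fast fiber onto the upper or lower sheet.

    Returns the voltage root of f(., c, n) on the target sheet (above V+ for
    ``upper``, below V- for ``lower``) where df/dV < 0.  Feeding fold-curve
    points realizes the fold projections P(L-) and P(L+).
    """
    if folds is None:
        folds = fold_voltages(p)
    if folds is None:
        raise ProjectionError("no folds: sheets are not distinguished")
    Vm, Vp = folds
    if target == "upper":
        lo, hi = Vp, V_SCAN_RANGE[1]
    elif target == "lower":
        lo, hi = V_SCAN_RANGE[0], Vm
    else:
        raise ValueError("target must be 'upper' or 'lower'")
    fun = lambda V: f_and_partials(V, c, n, p)[0]
    roots = _scan_roots(fun, lo, hi, n_grid=801)
    roots = [r for r in roots if f_and_partials(r, c, n, p)[1] < 0]
    if not roots:
        raise ProjectionError(
            f"no attracting root of f on {target} sheet for c={c}, n={n}")
    # the attracting root on a sheet is unique; keep the extreme one anyway
    return roots[-1] if target == "upper" else roots[0]


@dataclass(frozen=True)
class FoldCurves:
    """The two fold curves at constant voltage with n(c) parameterizations."""

    V_minus: float
    V_plus: float
    params: ModelParams

    @property
    def exists(self) -> bool:
        return True

    def n_minus(self, c):
        return n_on_fold(c, self.V_minus, self.params)

    def n_plus(self, c):
        return n_on_fold(c, self.V_plus, self.params)

    def sample(self, c_grid=None):
        """CSV-ready arrays (c, V, n, sheet_label) for both folds."""
        import pandas as pd

        if c_grid is None:
            c_grid = np.linspace(0.0, 1.4, 561)
        rows = []
        for label, V in (("L-", self.V_minus), ("L+", self.V_plus)):
            n = n_on_fold(c_grid, V, self.params)
            rows.append(pd.DataFrame(
                {"c": c_grid, "V": V, "n": n, "sheet_label": label}))
        return pd.concat(rows, ignore_index=True)


def fold_curves(p: ModelParams) -> FoldCurves | None:
    """Build :class:`FoldCurves`, or None when the folds have merged away."""
    folds = fold_voltages(p)
    if folds is None:
        return None
    return FoldCurves(V_minus=folds[0], V_plus=folds[1], params=p)
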