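"""One- and two-parameter bifurcation detection for the desingularized flow.

All detections are per-slice scalar bisections on smooth test functions
(no continuation machinery):

* TR (type II folded saddle-node, transcritical): the ordinary singularity
  crosses a fold curve; test function df/dV at the equilibrium.
* SN (type I folded saddle-node): two folded singularities on a fold line
  coalesce; test function is the extremal value of F along the fold (the
  double-root condition F = dF/dc = 0).
* focus <-> node: discriminant tr^2 - 4 det of the desingularized Jacobian
  at the tracked folded singularity.
* fold merge: double root of the fold-voltage function phi(V) (independent
  of g_K, which phi does not contain).
* delta = 0: sign change of the funnel-entry distance of the singular orbit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .desing import (
    F_of, desing_jacobian, find_folded_singularities,
    find_ordinary_singularities,
)
from .manifold import V_SCAN_RANGE, f_and_partials, fold_voltages, phi, phi_d1
from .orbit import UndefinedDeltaError, singular_orbit_delta
from .params import ModelParams

__all__ = [
    "BifurcationPoint", "NotFoundError", "find_TR", "find_SN",
    "find_focus_node", "find_fold_merge", "find_codim2_on_merge_line",
    "trace_delta_zero", "build_region_map", "mu_profile", "region_label",
]

_FOLD_INDEX = {"lower": 0, "upper": 1}


class NotFoundError(RuntimeError):
    """The test function does not change sign over the supplied bracket."""


@dataclass(frozen=True)
class BifurcationPoint:
    kind: str                 # TR | SN | focus_node | fold_merge | delta_zero | codim2
    gK: float
    gBK: float
    V: float | None = None
    c: float | None = None
    curve_id: str | None = None


def _set(p: ModelParams, param: str, value: float) -> ModelParams:
    if param not in ("gK", "gBK"):
        raise ValueError("sweep parameter must be 'gK' or 'gBK'")
    return p.replace(**{param: value})


def _bisect(test, bracket, xtol):
    a, b = bracket
    fa, fb = test(a), test(b)
    if not np.isfinite(fa) or not np.isfinite(fb) or fa * fb > 0:
        raise NotFoundError(
            f"no sign change of test function on bracket {bracket}")
    return brentq(test, a, b, xtol=xtol)


def _ordinary_on_fold_test(p: ModelParams, fold: str) -> float:
    """df/dV at the ordinary singularity nearest the given fold level.

    Vanishes exactly when the CN1 equilibrium sits on the fold (the
    transcritical / type II folded saddle-node condition)."""
    folds = fold_voltages(p)
    if folds is None:
        return np.nan
    Vf = folds[_FOLD_INDEX[fold]]
    ords = find_ordinary_singularities(p)
    if not ords:
        return np.nan
    s = min(ords, key=lambda s: abs(s.V - Vf))
    return f_and_partials(s.V, s.c, s.n, p)[1]


def find_TR(p: ModelParams, sweep: str, bracket, fold: str = "upper",
            xtol: float = 1e-6) -> BifurcationPoint:
    """Locate a transcritical (type II folded saddle-node) bifurcation."""
    val = _bisect(lambda x: _ordinary_on_fold_test(_set(p, sweep, x), fold),
                  bracket, xtol)
    q = _set(p, sweep, val)
    Vf = fold_voltages(q)[_FOLD_INDEX[fold]]
    s = min(find_ordinary_singularities(q), key=lambda s: abs(s.V - Vf))
    return BifurcationPoint("TR", q.gK, q.gBK, V=s.V, c=s.c,
                            curve_id=f"L_{'plus' if fold == 'upper' else 'minus'}")


def _extremal_F(p: ModelParams, V_line: float,
                window=(-1.0, 1.4), n_grid: int = 1201):
    """(c*, F(c*)) at the extremum of F along a constant-V fold line with the
    smallest |F| - the coalescing pair's midpoint near a saddle-node."""
    c = np.linspace(*window, n_grid)
    dFdc = np.array([desing_jacobian(V_line, ci, p)[0, 1] for ci in c])
    sign = np.sign(dFdc)
    best = None
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        cx = brentq(lambda cc: desing_jacobian(V_line, cc, p)[0, 1],
                    c[i], c[i + 1], xtol=1e-12)
        val = float(F_of(V_line, cx, p))
        if best is None or abs(val) < abs(best[1]):
            best = (cx, val)
    return best


def find_SN(p: ModelParams, sweep: str, bracket, fold: str = "upper",
            xtol: float = 1e-6, window=(-1.0, 1.4)) -> BifurcationPoint:
    """Locate a type I folded saddle-node (coalescence of a folded node and
    a folded saddle on one fold curve)."""
    def test(x):
        q = _set(p, sweep, x)
        folds = fold_voltages(q)
        if folds is None:
            return np.nan
        ext = _extremal_F(q, folds[_FOLD_INDEX[fold]], window)
        return np.nan if ext is None else ext[1]

    val = _bisect(test, bracket, xtol)
    q = _set(p, sweep, val)
    Vf = fold_voltages(q)[_FOLD_INDEX[fold]]
    cx, _ = _extremal_F(q, Vf, window)
    return BifurcationPoint("SN", q.gK, q.gBK, V=Vf, c=cx,
                            curve_id=f"L_{'plus' if fold == 'upper' else 'minus'}")


def find_focus_node(p: ModelParams, sweep: str, bracket,
                    fold: str = "lower", xtol: float = 1e-6) -> BifurcationPoint:
    """Locate the focus <-> node transition of the folded singularities on a
    fold curve (zero of the eigenvalue discriminant)."""
    curve = f"L_{'plus' if fold == 'upper' else 'minus'}"

    def disc(x):
        q = _set(p, sweep, x)
        sings = [s for s in find_folded_singularities(q)
                 if s.on_curve == curve]
        if not sings:
            return np.nan
        vals = []
        for s in sings:
            J = desing_jacobian(s.V, s.c, q)
            tr = J[0, 0] + J[1, 1]
            vals.append(tr * tr - 4.0 * np.linalg.det(J))
        return max(vals)

    val = _bisect(disc, bracket, xtol)
    q = _set(p, sweep, val)
    Vf = fold_voltages(q)[_FOLD_INDEX[fold]]
    return BifurcationPoint("focus_node", q.gK, q.gBK, V=Vf, curve_id=curve)


def _extremal_phi(p: ModelParams):
    """(V*, phi(V*)) at the extremum of phi with smallest |phi|."""
    V = np.linspace(*V_SCAN_RANGE, 4001)
    d = phi_d1(V, p)
    sign = np.sign(d)
    best = None
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        vx = brentq(lambda vv: phi_d1(vv, p), V[i], V[i + 1], xtol=1e-12)
        val = float(phi(vx, p))
        if best is None or abs(val) < abs(best[1]):
            best = (vx, val)
    return best


def find_fold_merge(p: ModelParams, bracket=(20.0, 40.0),
                    xtol: float = 1e-8) -> BifurcationPoint:
    """g_BK at which the two fold curves merge (double root of phi).

    phi contains neither g_K nor c, so the merge value is independent of
    both."""
    def test(gBK):
        ext = _extremal_phi(p.replace(gBK=gBK))
        return np.nan if ext is None else ext[1]

    val = _bisect(test, bracket, xtol)
    q = p.replace(gBK=val)
    Vstar, _ = _extremal_phi(q)
    return BifurcationPoint("fold_merge", q.gK, val, V=Vstar)


def find_codim2_on_merge_line(p: ModelParams, bracket=(60.0, 100.0),
                              xtol: float = 1e-6) -> BifurcationPoint:
    """g_K at which the folded singularities disappear from the merged fold
    line (SN3/SN4 coalescence): double root of F along the line V = V*."""
    merge = find_fold_merge(p)
    q0 = p.replace(gBK=merge.gBK)

    def test(gK):
        ext = _extremal_F(q0.replace(gK=gK), merge.V)
        return np.nan if ext is None else ext[1]

    val = _bisect(test, bracket, xtol)
    ext = _extremal_F(q0.replace(gK=val), merge.V)
    return BifurcationPoint("codim2", val, merge.gBK, V=merge.V, c=ext[0])


def trace_delta_zero(p: ModelParams, gBK_values, gK_bracket=(3.0, 7.0),
                     xtol: float = 1e-4) -> pd.DataFrame:
    """Per-g_BK bisection on the funnel distance delta of the singular orbit.

    Returns a polyline (gK, gBK) of the delta = 0 curve, the right-hand
    border of the mixed-mode-oscillation band.  Slices where delta is
    undefined over the whole bracket are skipped.
    """
    rows = []
    for gBK in np.atleast_1d(gBK_values):
        def d(gK):
            return singular_orbit_delta(p.replace(gK=gK, gBK=gBK))
        try:
            gK0 = _bisect(d, gK_bracket, xtol)
        except (NotFoundError, UndefinedDeltaError):
            continue
        rows.append({"curve_id": "delta_zero", "gK": gK0, "gBK": gBK})
    return pd.DataFrame(rows, columns=["curve_id", "gK", "gBK"])


def mu_profile(p: ModelParams, gK_values) -> pd.DataFrame:
    """Eigenvalue ratio mu and oscillation bound s_max of the folded node on
    L+ over a g_K grid (NaN where no folded node exists)."""
    rows = []
    for gK in np.atleast_1d(gK_values):
        q = p.replace(gK=gK)
        fns = [s for s in find_folded_singularities(q)
               if s.on_curve == "L_plus" and s.classification == "folded_node"]
        mu = fns[0].mu if fns else np.nan
        smax = fns[0].s_max if fns else None
        rows.append({"gK": float(gK), "mu": mu, "s_max": smax})
    return pd.DataFrame(rows)


def region_label(p: ModelParams) -> str:
    """Qualitative region of the two-parameter diagram at one point.

    A: depolarized steady state (stable equilibrium on the upper sheet);
    B: folded node on L+ (mixed-mode-capable); C: folded singularities on
    L- only; D: hyperpolarized steady with a negative-c folded node on L-;
    E: hyperpolarized steady without folded singularities; no_folds: the
    manifold has no fold.
    """
    folds = fold_voltages(p)
    if folds is None:
        return "no_folds"
    Vm, Vp = folds
    sings = find_folded_singularities(p)
    ords = find_ordinary_singularities(p)
    if any(s.on_curve == "L_plus" and s.classification == "folded_node"
           and "nonphysical" not in s.flags for s in sings):
        return "B"
    stable = [s for s in ords if s.classification in
              ("stable_node", "stable_focus")]
    if any(s.V > Vp for s in stable):
        return "A"
    if any(s.V < Vm for s in stable):
        neg_fn = any(s.on_curve == "L_minus"
                     and s.classification == "folded_node" and s.c < 0
                     for s in sings)
        return "D" if neg_fn else "E"
    return "C"


def build_region_map(p: ModelParams, gK_values, gBK_values) -> pd.DataFrame:
    """Label a (g_K, g_BK) grid by :func:`region_label`."""
    rows = []
    for gBK in np.atleast_1d(gBK_values):
        for gK in np.atleast_1d(gK_values):
            rows.append({"gK": float(gK), "gBK": float(gBK),
                         "label": region_label(p.replace(gK=gK, gBK=gBK))})
    return pd.DataFrame(rows)
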