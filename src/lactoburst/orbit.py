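"""Singular periodic orbits, the strong canard, and the funnel distance delta.

In the singular limit the attractor is pieced together from slow segments of
the reduced flow on the attracting sheets of the critical manifold and fast
vertical jumps along the voltage fibers at the fold curves: the trajectory
drifts down the lower sheet until it reaches L-, jumps up to the projection
curve P(L-) on the upper sheet, drifts until it reaches L+ (or funnels into
the folded node FN), and jumps back down to P(L+).

Whether the jump-up point on P(L-) lies inside the singular funnel - the
region bounded by the strong canard (SC) and L+ whose trajectories all pass
through the FN - decides the character of the perturbed orbit: funnel entry
(delta > 0) yields canard-induced mixed-mode oscillations (pseudo-plateau
bursting), landing outside (delta < 0) yields relaxation/spiking.  delta is
measured here as a signed c-coordinate difference along P(L-) between the
orbit's landing point and the SC crossing; the zero set is the same as for
an arc-length convention and only the sign is used by the theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .desing import Singularity, desing_jacobian, desing_rhs, find_folded_singularities
from .manifold import ProjectionError, fold_voltages, n_of, project_to_sheet
from .params import ModelParams

__all__ = [
    "OrbitSegment", "SingularOrbit", "StrongCanard", "RunawayError",
    "UndefinedDeltaError", "integrate_reduced", "strong_canard",
    "build_singular_orbit", "delta_of", "singular_orbit_delta",
]

# weights used for the mixed-unit (V, c) distance near the folded node
_V_SCALE = 40.0   # mV
_C_SCALE = 1.0    # uM
_FN_TOL = 1e-4    # scaled distance at which the FN is considered reached
_C_SPAN = (-0.25, 1.6)  # runaway guard on the Ca2+ coordinate (uM)


class RunawayError(RuntimeError):
    """Reduced-flow trajectory diverged or left the tracked c-range."""


class UndefinedDeltaError(RuntimeError):
    """delta is undefined (no strong canard, or SC does not reach P(L-))."""


@dataclass
class OrbitSegment:
    sheet: str                 # 'upper' | 'lower'
    V: np.ndarray
    c: np.ndarray
    n: np.ndarray


@dataclass
class StrongCanard:
    """Backward-integrated strong-eigendirection path ending at the FN."""

    V: np.ndarray
    c: np.ndarray
    fn: Singularity
    eigendirection: np.ndarray
    c_at_PLminus: float | None   # c where the SC crosses P(L-), if it does


@dataclass
class SingularOrbit:
    segments: list[OrbitSegment]
    jumps: list[dict]
    delta: float | None
    passes_through_FN: bool
    converged: bool
    landing_c: float | None = None    # c of the jump-up point on P(L-)
    sc_c: float | None = None         # c of SC x P(L-)
    fn: Singularity | None = None


def _folded_node_on_Lplus(p: ModelParams) -> Singularity | None:
    sings = find_folded_singularities(p)
    nodes = [s for s in sings
             if s.on_curve == "L_plus" and s.classification == "folded_node"]
    if not nodes:
        return None
    # prefer the physical one if several
    nodes.sort(key=lambda s: (("nonphysical" in s.flags), -s.c))
    return nodes[0]


def _plminus_spline(p: ModelParams, folds, c_grid=None) -> CubicSpline:
    """Interpolant V = P(L-)(c): the upper-sheet projection of L-."""
    if c_grid is None:
        c_grid = np.linspace(_C_SPAN[0] + 0.05, _C_SPAN[1] - 0.05, 160)
    Vm = folds[0]
    Vs, cs = [], []
    for c in c_grid:
        try:
            Vs.append(project_to_sheet(c, n_of(c, Vm, p), "upper", p, folds))
            cs.append(c)
        except ProjectionError:
            continue
    if len(cs) < 4:
        raise UndefinedDeltaError("P(L-) could not be constructed")
    return CubicSpline(np.asarray(cs), np.asarray(Vs))


def integrate_reduced(start, sheet: str, p: ModelParams,
                      folds=None, fn: Singularity | None = None,
                      t_max: float = 5e7, rtol: float = 1e-10):
    """Integrate the reduced (desingularized) flow on an attracting sheet.

    Runs in rescaled time tau, which coincides with true time on attracting
    sheets, until the trajectory reaches the sheet's fold curve (or, on the
    upper sheet, funnels to within tolerance of the folded node ``fn``).
    Returns ``(path_V, path_c, reason)`` with reason in
    {'fold', 'fn', 'fixed_point'}.
    """
    if folds is None:
        folds = fold_voltages(p)
    if folds is None:
        raise RunawayError("no fold curves")
    V_fold = folds[1] if sheet == "upper" else folds[0]

    def rhs(t, y):
        return desing_rhs(y[0], y[1], p)

    def ev_fold(t, y):
        return y[0] - V_fold
    ev_fold.terminal = True

    def ev_runaway(t, y):
        return (y[1] - _C_SPAN[0]) * (_C_SPAN[1] - y[1])
    ev_runaway.terminal = True

    events = [ev_fold, ev_runaway]
    if sheet == "upper" and fn is not None:
        def ev_fn(t, y):
            return np.hypot((y[0] - fn.V) / _V_SCALE,
                            (y[1] - fn.c) / _C_SCALE) - _FN_TOL
        ev_fn.terminal = True
        events.append(ev_fn)

    sol = solve_ivp(rhs, (0.0, t_max), np.asarray(start, dtype=float),
                    method="LSODA", rtol=rtol, atol=1e-12, events=events,
                    dense_output=False, max_step=t_max / 50)
    if sol.t_events[1].size:
        raise RunawayError(f"trajectory left c-range on {sheet} sheet")
    if sol.t_events[0].size:
        reason = "fold"
    elif len(events) == 3 and sol.t_events[2].size:
        reason = "fn"
    elif sol.status == 0:
        reason = "fixed_point"   # ran out the clock without hitting a fold
    else:
        raise RunawayError(f"integration failed on {sheet} sheet: {sol.message}")
    return sol.y[0], sol.y[1], reason


def strong_canard(p: ModelParams, eps: float = 1e-4) -> StrongCanard:
    """The strong canard: backward orbit from the FN along the strong
    eigendirection, kept on the upper attracting sheet, traced until it
    crosses P(L-) or leaves the sampled c-range."""
    fn = _folded_node_on_Lplus(p)
    if fn is None:
        raise UndefinedDeltaError("no folded node on L+")
    folds = fold_voltages(p)
    J = desing_jacobian(fn.V, fn.c, p)
    lam, vecs = np.linalg.eig(J)
    strong = int(np.argmax(np.abs(lam.real)))
    v = np.real(vecs[:, strong])
    v = v / np.hypot(v[0] / _V_SCALE, v[1] / _C_SCALE)

    spline = _plminus_spline(p, folds)
    lo, hi = spline.x[0], spline.x[-1]

    def rhs(t, y):
        dV, dc = desing_rhs(y[0], y[1], p)
        return (-dV, -dc)   # backward in tau

    def ev_plminus(t, y):
        c = min(max(y[1], lo), hi)
        return y[0] - float(spline(c))
    ev_plminus.terminal = True

    def ev_fold(t, y):
        return y[0] - folds[1]
    ev_fold.terminal = True

    def ev_crange(t, y):
        return (y[1] - lo) * (hi - y[1])
    ev_crange.terminal = True

    best = None
    for sign in (+1.0, -1.0):
        y0 = np.array([fn.V + sign * eps * v[0], fn.c + sign * eps * v[1]])
        if y0[0] <= folds[1]:   # keep the branch on the upper sheet
            continue
        sol = solve_ivp(rhs, (0.0, 5e7), y0, method="LSODA", rtol=1e-10,
                        atol=1e-12, events=[ev_plminus, ev_fold, ev_crange])
        c_cross = float(sol.y[1, -1]) if sol.t_events[0].size else None
        cand = (sol.y[0], sol.y[1], c_cross)
        if best is None or (c_cross is not None and best[2] is None):
            best = cand
    if best is None:
        raise UndefinedDeltaError("no upper-sheet branch of the strong canard")
    V_path, c_path, c_cross = best
    return StrongCanard(V=V_path, c=c_path, fn=fn, eigendirection=v,
                        c_at_PLminus=c_cross)


def _in_funnel(V0: float, c0: float, p: ModelParams, folds,
               fn: Singularity) -> bool:
    """Does the upper-sheet trajectory from (V0, c0) pass through the FN?"""
    _, _, reason = integrate_reduced((V0, c0), "upper", p, folds, fn=fn)
    return reason == "fn"


def build_singular_orbit(p: ModelParams, c_start: float | None = None,
                         max_cycles: int = 50,
                         tol: float = 1e-8) -> SingularOrbit:
    """Construct the singular periodic orbit by iterating the one-dimensional
    return map in the c-coordinate of the jump-down point on P(L+).

    Jumps preserve (c, n) and move only V (fast fibers).  When the upper
    segment funnels into the folded node, the jump down is taken from the
    FN's (c, n), since in the singular limit the orbit leaves at the FN.
    Non-convergence within ``max_cycles`` is reported, not raised (steady
    regions have no closed orbit).
    """
    folds = fold_voltages(p)
    if folds is None:
        raise RunawayError("no fold curves: no singular orbit")
    Vm, Vp = folds
    fn = _folded_node_on_Lplus(p)

    try:
        sc = strong_canard(p)
        sc_c = sc.c_at_PLminus
    except UndefinedDeltaError:
        sc, sc_c = None, None

    c_down = c_start if c_start is not None else (fn.c if fn else 0.5)
    segments: list[OrbitSegment] = []
    jumps: list[dict] = []
    converged = False
    passes_fn = False
    landing_c = None
    for cycle in range(max_cycles):
        segments, jumps = [], []   # keep only the last cycle
        # jump down from L+ (or FN) to the lower sheet
        n_down = n_of(c_down, Vp, p)
        V_low = project_to_sheet(c_down, n_down, "lower", p, folds)
        jumps.append({"from": "L_plus", "c": c_down, "V_from": Vp,
                      "V_to": V_low})
        V_path, c_path, reason = integrate_reduced((V_low, c_down), "lower",
                                                   p, folds)
        segments.append(OrbitSegment("lower", V_path, c_path,
                                     n_of(c_path, V_path, p)))
        if reason == "fixed_point":
            return SingularOrbit(segments, jumps, None, False, False, fn=fn)
        c_up = float(c_path[-1])
        landing_c = c_up
        # jump up from L- to the upper sheet (onto P(L-))
        n_up = n_of(c_up, Vm, p)
        V_high = project_to_sheet(c_up, n_up, "upper", p, folds)
        jumps.append({"from": "L_minus", "c": c_up, "V_from": Vm,
                      "V_to": V_high})
        V_path, c_path, reason = integrate_reduced((V_high, c_up), "upper",
                                                   p, folds, fn=fn)
        segments.append(OrbitSegment("upper", V_path, c_path,
                                     n_of(c_path, V_path, p)))
        if reason == "fixed_point":
            return SingularOrbit(segments, jumps, None, False, False, fn=fn)
        passes_fn = reason == "fn"
        c_next = float(fn.c) if passes_fn else float(c_path[-1])
        if abs(c_next - c_down) < tol:
            c_down = c_next
            converged = True
            break
        c_down = c_next

    delta = None
    if converged and sc_c is not None and landing_c is not None:
        inside = passes_fn or _in_funnel(
            float(segments[-1].V[0]), landing_c, p, folds, fn)
        delta = abs(landing_c - sc_c) * (1.0 if inside else -1.0)
    return SingularOrbit(segments, jumps, delta, passes_fn, converged,
                         landing_c=landing_c, sc_c=sc_c, fn=fn)


def delta_of(orbit: SingularOrbit) -> float:
    """Signed funnel-entry distance of a converged singular orbit."""
    if not orbit.converged:
        raise UndefinedDeltaError("orbit did not converge")
    if orbit.delta is None:
        raise UndefinedDeltaError("strong canard does not reach P(L-)")
    return orbit.delta


def singular_orbit_delta(p: ModelParams) -> float:
    """Convenience: build the singular orbit and return its delta."""
    return delta_of(build_singular_orbit(p))
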