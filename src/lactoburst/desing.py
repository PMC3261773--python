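"""Reduced/desingularized flow on the critical manifold and its singularities.

Eliminating n via the critical-manifold relation and rescaling time by
-(df/dV)^-1 removes the singularity of the reduced flow at the folds.  The
desingularized system in (V, c) is

    dV/dtau = F(V, c)
    dc/dtau = fc (alpha I_Ca + kc c) * df/dV

with F = -fc (alpha I_Ca + kc c) df/dc + ((n_inf - n)/tau_n) df/dn, all
partials evaluated on the manifold (n = n_of(c, V)).  The rescaling reverses
time on the repelling middle sheet.

Equilibria come in two kinds: ordinary singularities (true equilibria of the
full model, lying on the c-nullcline branch CN1 where alpha I_Ca + kc c = 0)
and folded singularities (points on a fold curve where F = 0).  Folded
singularities are classified by the eigenvalues of the 2x2 Jacobian: folded
node (real, same sign), folded saddle (real, opposite signs), folded focus
(complex).  For a folded node the eigenvalue ratio mu = lambda_weak /
lambda_strong in (0, 1] bounds the number of small canard-induced
oscillations via s_max = floor((mu + 1) / (2 mu)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import boltzmann, boltzmann_d1, hill2, hill2_d1, hill2_d2
from .params import ModelParams
from .manifold import (
    V_SCAN_RANGE, _AB, f_and_partials, fold_voltages, n_of, phi, phi_d1,
)

__all__ = [
    "Singularity", "F_of", "desing_rhs", "desing_jacobian",
    "find_ordinary_singularities", "find_folded_singularities",
    "mu_of", "s_max_of", "classify_2x2", "DEFAULT_C_RANGE",
]

DEFAULT_C_RANGE = (0.0, 1.4)   # uM, covers the physiological Ca2+ window
NEGATIVE_C_RANGE = (-1.0, 0.0)  # extended, nonphysical window


@dataclass
class Singularity:
    """An ordinary or folded singularity of the desingularized flow."""

    kind: str                      # 'ordinary' | 'folded'
    V: float
    c: float
    n: float
    on_curve: str                  # 'CN1' | 'L_plus' | 'L_minus'
    classification: str
    eigenvalues: tuple[complex, complex]
    mu: float | None = None
    s_max: int | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def location(self) -> tuple[float, float, float]:
        return (self.V, self.c, self.n)


def _H(V, c, p: ModelParams):
    """fc (alpha I_Ca + kc c); the full-model dc/dt is -H."""
    ICa = p.gCa * boltzmann(V, p.vm, p.sm) * (V - p.VCa)
    return p.fc * (p.alpha * ICa + p.kc * c)


def _fV_manifold(V, p: ModelParams):
    """df/dV evaluated on the manifold: equals -phi(V)/(V - V_K)."""
    return -phi(V, p) / (V - p.VK)


def F_of(V, c, p: ModelParams):
    """Desingularized V-velocity F with n eliminated via the manifold."""
    H = _H(V, c, p)
    ninf = boltzmann(V, p.vn, p.sn)
    nman = n_of(c, V, p)
    # -H * df/dc + ((ninf - n)/taun) * df/dn, on the manifold
    return (H * p.gKCa * hill2_d1(c, p.Kd) * (V - p.VK)
            - (p.gK * (V - p.VK) / p.taun) * (ninf - nman))


def desing_rhs(V, c, p: ModelParams):
    """(dV/dtau, dc/dtau) of the desingularized system.

    dc/dtau vanishes on the fold curves (df/dV = 0) and on CN1
    (alpha I_Ca + kc c = 0).  On attracting sheets (df/dV < 0) the rescaled
    time runs with true time; on the middle sheet it is reversed.
    """
    return F_of(V, c, p), _H(V, c, p) * _fV_manifold(V, p)


def desing_jacobian(V, c, p: ModelParams):
    """Analytic 2x2 Jacobian of :func:`desing_rhs` with respect to (V, c).

    Closed form, derived from the same building blocks as the vector field;
    accuracy matters here because the folded-node eigenvalue ratio stays
    below about 0.07 for the default cell.
    """
    VK = p.VK
    dVK = V - VK
    A, dA, _, _, _, _ = _AB(V, p)
    sp = hill2_d1(c, p.Kd)
    spp = hill2_d2(c, p.Kd)
    ninf = boltzmann(V, p.vn, p.sn)
    dninf = boltzmann_d1(V, p.vn, p.sn)
    nman = n_of(c, V, p)

    H = p.fc * (p.alpha * A + p.kc * c)
    H_V = p.fc * p.alpha * dA
    H_c = p.fc * p.kc

    FV = -phi(V, p) / dVK                      # df/dV on the manifold
    FV_V = -(phi_d1(V, p) * dVK - phi(V, p)) / (dVK * dVK)
    n_V = FV / (p.gK * dVK)
    n_c = -(p.gKCa / p.gK) * sp

    F_V = (H_V * p.gKCa * sp * dVK + H * p.gKCa * sp
           - (p.gK / p.taun) * (ninf - nman)
           - (p.gK * dVK / p.taun) * (dninf - n_V))
    F_c = (H_c * p.gKCa * sp * dVK + H * p.gKCa * spp * dVK
           + (p.gK * dVK / p.taun) * n_c)
    G_V = H_V * FV + H * FV_V
    G_c = H_c * FV
    return np.array([[F_V, F_c], [G_V, G_c]])


def classify_2x2(J: np.ndarray, folded: bool) -> tuple[str, tuple[complex, complex]]:
    """Label an equilibrium from its 2x2 Jacobian (spectral classification)."""
    eig = np.linalg.eigvals(J)
    eig = tuple(sorted(eig, key=lambda z: abs(z)))
    l1, l2 = eig
    real = abs(l1.imag) < 1e-12 * max(1.0, abs(l1)) and \
        abs(l2.imag) < 1e-12 * max(1.0, abs(l2))
    prefix = "folded_" if folded else ""
    if real:
        r1, r2 = l1.real, l2.real
        if r1 * r2 < 0:
            return prefix + "saddle", eig
        if folded:
            return "folded_node", eig
        return ("stable_node" if r2 < 0 else "unstable_node"), eig
    if folded:
        return "folded_focus", eig
    return ("stable_focus" if l1.real < 0 else "unstable_focus"), eig


def mu_of(sing: Singularity) -> float:
    """Eigenvalue ratio weak/strong of a folded node or saddle."""
    l1, l2 = sing.eigenvalues
    if abs(l1.imag) > 0 or abs(l2.imag) > 0:
        raise ValueError("mu is undefined for complex eigenvalues (focus)")
    return l1.real / l2.real


def s_max_of(mu: float) -> int:
    """Maximal small-oscillation count floor((mu + 1)/(2 mu)) for mu in (0, 1]."""
    if not 0.0 < mu <= 1.0:
        raise ValueError("s_max requires mu in (0, 1]")
    return math.floor((mu + 1.0) / (2.0 * mu))


def _attach_mu(sing: Singularity) -> None:
    l1, l2 = sing.eigenvalues
    if abs(l1.imag) == 0 and abs(l2.imag) == 0 and l2.real != 0:
        sing.mu = l1.real / l2.real
        if 0.0 < sing.mu <= 1.0:
            sing.s_max = s_max_of(sing.mu)


def find_ordinary_singularities(p: ModelParams) -> list[Singularity]:
    """All equilibria of the full model (on CN1), classified in the
    desingularized flow.

    At an equilibrium n = n_inf(V) and c = -alpha I_Ca / kc, so equilibria
    are voltage roots of f(V, c(V), n_inf(V)); found by dense sign-scan plus
    bisection.  Negative-c locations are flagged 'nonphysical'.
    """
    def cstar(V):
        ICa = p.gCa * boltzmann(V, p.vm, p.sm) * (V - p.VCa)
        return -p.alpha * ICa / p.kc

    def h(V):
        return f_and_partials(V, cstar(V), boltzmann(V, p.vn, p.sn), p)[0]

    V_grid = np.linspace(*V_SCAN_RANGE, 4001)
    vals = h(V_grid)
    out: list[Singularity] = []
    sign = np.sign(vals)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        V = brentq(h, V_grid[i], V_grid[i + 1], xtol=1e-12)
        c = float(cstar(V))
        n = float(boltzmann(V, p.vn, p.sn))
        label, eig = classify_2x2(desing_jacobian(V, c, p), folded=False)
        flags = ("nonphysical",) if c < 0 else ()
        s = Singularity("ordinary", float(V), c, n, "CN1", label, eig,
                        flags=flags)
        _attach_mu(s)
        out.append(s)
    return out


def find_folded_singularities(
    p: ModelParams,
    c_range: tuple[float, float] = DEFAULT_C_RANGE,
    include_negative_c: bool = True,
    n_grid: int = 801,
) -> list[Singularity]:
    """Folded singularities on both fold curves: c-roots of F on each fold.

    The search covers ``c_range`` plus (if requested) an extended negative-c
    window whose hits are flagged 'nonphysical'.  A pair of roots closer than
    1e-8 uM is merged and flagged 'degenerate'.
    """
    folds = fold_voltages(p)
    if folds is None:
        return []
    out: list[Singularity] = []
    windows = [(c_range, ())]
    if include_negative_c:
        windows.append((NEGATIVE_C_RANGE, ("nonphysical",)))
    for (curve, Vf) in (("L_minus", folds[0]), ("L_plus", folds[1])):
        for (lo, hi), base_flags in windows:
            c_grid = np.linspace(lo, hi, n_grid)
            vals = F_of(Vf, c_grid, p)
            sign = np.sign(vals)
            roots = []
            for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
                roots.append(brentq(lambda c: F_of(Vf, c, p),
                                    c_grid[i], c_grid[i + 1], xtol=1e-13))
            merged: list[tuple[float, tuple[str, ...]]] = []
            for r in sorted(roots):
                if merged and abs(r - merged[-1][0]) < 1e-8:
                    merged[-1] = ((r + merged[-1][0]) / 2,
                                  base_flags + ("degenerate",))
                else:
                    merged.append((r, base_flags))
            for c, flags in merged:
                n = float(n_of(c, Vf, p))
                label, eig = classify_2x2(desing_jacobian(Vf, c, p),
                                          folded=True)
                s = Singularity("folded", float(Vf), float(c), n, curve,
                                label, eig, flags=flags)
                _attach_mu(s)
                out.append(s)
    return out
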