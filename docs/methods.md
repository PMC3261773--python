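# Methods

## The model

The package analyses a three-variable conductance-based model of a
pituitary lactotroph, a cell type whose electrical activity is
*pseudo-plateau bursting*: short bursts of small spikes riding on a
depolarized plateau. The variables are the membrane potential `V` (mV), the
delayed-rectifier K⁺ activation `n`, and the cytosolic free Ca²⁺
concentration `c` (μM):

```
Cm dV/dt = −(I_Ca + I_K + I_KCa + I_BK)
   dn/dt = (n∞(V) − n)/τn
   dc/dt = −fc (α I_Ca + kc c)
```

with `I_Ca = gCa m∞(V)(V − VCa)` and three K⁺ currents proportional to
`(V − VK)`: the delayed rectifier (`gK n`), an SK-type Ca²⁺-activated
current (`gKCa s∞(c)` with `s∞` a Hill function, exponent 2, half-max `Kd`),
and a fast BK-type current (`gBK b∞(V)`). All activation curves are
Boltzmann functions. Units are fixed (mV, ms, pF, nS, pA, μM); since
nS·mV = pA and pF/nS = ms there are no hidden conversion factors.

Time scales for the default cell: τ_V ≈ 1.7–10 ms (= Cm/g_total along a
burst), τ_n = 43 ms, τ_c = 1/(fc·kc) = 625 ms. `V` is therefore treated as
the single fast variable and `(n, c)` as slow, with the capacitance `Cm`
playing the role of the singular perturbation parameter. The default
parameters are the standard lactotroph set; `(Cm, gK, gBK)` are the
designated bifurcation parameters.

## One-fast/two-slow reduction

In the limit `Cm → 0` trajectories collapse onto the critical manifold
`f(V, c, n) = 0`, where `f` is the total ionic current. Because `f` is
linear in the lumped conductance `gK n + gKCa s∞(c)`, two simplifications
are exact:

* the manifold is the graph `n = n(c, V)` (module `manifold.n_of`);
* the fold condition `f = 0, ∂f/∂V = 0` reduces to one scalar equation
  `φ(V) = (A′+B′)(V−VK) − (A+B) = 0` with `A = I_Ca`, `B = I_BK`, so the
  folds `L±` are two constant-voltage lines `V−  < V+`, independent of both
  `c` and `gK`. They merge and disappear at large `gBK` (double root of φ).

The reduced flow on the manifold, rescaled by `−(∂f/∂V)⁻¹`, gives the
desingularized system in `(V, c)` (module `desing`), whose equilibria are
the *ordinary singularities* (true equilibria of the full model, on the
`c`-nullcline branch CN1) and the *folded singularities* (zeros of the
desingularized `V`-velocity `F` on a fold line). Folded nodes admit an
eigenvalue ratio `μ = λ_weak/λ_strong ∈ (0, 1]` and the rotation bound
`s_max = floor((μ+1)/(2μ))`: the maximal number of small canard-induced
oscillations of a nearby trajectory.

All Jacobians (3×3 full, 2×2 desingularized, 2×2 fast-subsystem) are
closed-form analytic expressions, hand-derived from the same building
blocks as the vector fields and validated against central finite
differences in the test suite. Analytic accuracy matters because `μ` stays
below ≈0.07 for the default cell, so the weak eigenvalue is a small
difference of nearly equal quantities.

## Root finding and bifurcation detection

Every root search is a dense sign-scan followed by bisection (`brentq`,
typically to 1e-10 or better); there is no Newton iteration from arbitrary
seeds and no continuation machinery. This guarantees that all roots inside
the scan window are found and behaves robustly near double roots. Scan
windows: `V ∈ [−75, 50]` mV (between the reversal potentials) with 2001–4001
points; `c ∈ [0, 1.4]` μM (561+ points) plus an extended window `[−1, 0)`
whose hits are flagged `nonphysical` (the negative-`c` folded nodes are a
real feature of the desingularized phase portrait at large `gK`).

Codimension-one events are zeros of scalar test functions of one parameter:

* **Transcritical / type II folded saddle-node (TR):** `∂f/∂V` at the
  ordinary singularity nearest the relevant fold — zero exactly when the
  equilibrium sits on the fold.
* **Type I folded saddle-node (SN):** the extremal value of `F` along the
  fold line (located as the zero of `dF/dc`, an entry of the analytic
  Jacobian) — the double-root condition `F = dF/dc = 0`. Using the
  extremum rather than a root count avoids the resolution bias of a grid
  scan when the coalescing roots are closer than the grid spacing. Along a
  constant-`V` fold line `dF/dc` happens to be independent of `gK` (the
  `gK` dependence of `F` is an additive constant), which makes this test
  function particularly well conditioned.
* **Focus↔node:** the eigenvalue discriminant `tr² − 4 det` of the
  desingularized Jacobian at the tracked folded singularity.
* **Fold merge:** the extremal value of `φ` (double root of the
  fold-voltage equation); independent of `gK`, which `φ` does not contain.
* **Codimension-2 point:** with `gBK` held at the merge value, the
  double-root condition of `F` along the merged fold line, bisected in `gK`.

## Singular orbits and the funnel distance δ

The singular periodic orbit alternates slow segments of the desingularized
flow on the attracting sheets with instantaneous vertical jumps (constant
`(c, n)`, only `V` changes) at the folds, constructed by iterating the 1-D
return map in the `c`-coordinate of the jump-down point until it repeats to
1e-8 μM (at most 50 cycles; non-convergence is reported, not raised — steady
regions have no closed orbit). When the upper-sheet segment funnels into
the folded node, integration stops at a scaled distance 1e-4 from it and
the jump down is taken from the node's `(c, n)`, since in the singular
limit the orbit leaves at the folded node.

The strong canard is integrated backward in rescaled time from the folded
node offset by ε = 1e-4 along the strong eigenvector (both signs tried, the
upper-sheet branch kept). δ is the signed `c`-difference along P(L−) — the
projection of the lower fold onto the upper sheet, represented as a cubic
spline over ~160 projected points — between the orbit's jump-up point and
the strong-canard crossing. The sign is fixed by direct funnel membership:
the landing point is integrated forward and δ > 0 iff that trajectory
reaches the folded node. Measuring δ as a coordinate difference rather
than arc length is a convention; the zero set (all the theory uses) is
identical. Reduced-flow integration uses LSODA at rtol 1e-10 with terminal
events on the fold voltage (and the runaway guard `c ∈ [−0.25, 1.6]`).

δ > 0 together with a folded node predicts mixed-mode oscillations
(pseudo-plateau bursting) of the full system; δ < 0 predicts relaxation
spiking. The package verifies both directions by simulation at
`Cm = 0.5` and 10 pF.

## Full-system simulation and burst features

The full model is integrated with LSODA and the analytic Jacobian
(rtol 1e-8, atol 1e-10), default horizon 60 s of model time with a 20 s
discarded transient, output sampled at 0.5 ms (0.25 ms for feature-sensitive
runs), doubled automatically when fewer than 3 periods are detected.
Default initial state `(−60 mV, 0.1, 0.1 μM)`.

Feature extraction works period by period, with the period defined by
minima of `c` — the slowest variable — accepted only when their prominence
exceeds 30% of the full `c` range (small intra-burst Ca²⁺ ripples must not
split a burst). Spikes are voltage maxima above the active-phase threshold
(−40 mV; pseudo-plateau silent phases sit well below it) with prominence
above a floor. Regime labels: *steady* (total V range < 1 mV), *spiking*
(≤1 spike per period), *bursting* (≥2).

**The spike-prominence floor.** The default floor is 1e-3 mV, i.e. just
above the integration error, so every resolvable canard rotation counts as
a spike. This is a deliberate choice: near the Hopf-side border of the
bursting region the rotation amplitudes decay through four orders of
magnitude mid-burst (from mV to ~1e-4 mV) before growing back, and any
chart-scale floor (e.g. 0.5 mV) undercounts there by a factor of ~4 while
leaving counts elsewhere unchanged. One floor then reproduces both ends of
the published burst-feature map: 3 spikes/burst at `(gK, gBK) = (6, 1)` nS
and a maximum of ≈33 spikes/burst with an ≈8.3 s active phase at the border
near `(0.73, 0.4)` nS (both at `Cm = 5` pF). A stricter floor remains one
config field away. For noisy traces the floor rises automatically to
8× a robust noise estimate (1.4826·MAD of the second difference / √6,
which is ~σ for white noise but ~0 for a smooth solver trace), which is
what makes exact spike-count recovery on the synthetic fixtures possible
up to 0.5 mV noise.

**Locating the maximum spikes per burst.** Burst duration, and with it the
rotation count, grows toward the Hopf-side border and collapses to
small-amplitude spiking just across it; a uniform grid undersamples the
maximum badly. `max_spikes_scan` therefore walks each `gBK` slice upward in
`gK` until bursting appears, bisects the spiking/bursting border (10
iterations), and measures counts just inside it with a 200 s horizon.
Default slices `gBK ∈ {0.4, 0.8, 1.2, 1.6, 2.0}` nS; the scan costs ~2 min
on one CPU. Sizes were chosen so the whole analysis pipeline remains a
desk-scale computation.

## Two-fast/one-slow comparison (z-curve)

`zcurve` freezes `c` and sweeps the `(V, n)` fast-subsystem equilibria,
bisecting for limit points (root-count changes) and Hopf points (complex
pair of the 2×2 Jacobian crossing the axis). Hopf criticality is labeled
by probing: integrating from a tiny perturbation on the unstable side and
asking whether the growth saturates in a small cycle (supercritical) or
escapes to a distant attractor (subcritical). This avoids a first-Lyapunov
coefficient computation; the label is only used qualitatively. Fast
periodic branches are not continued — their existence is probed by the same
simulations. The point of the module is the negative result: the
spiking↔bursting transition of the full system is invisible in the z-curve
picture but is exactly the δ = 0 crossing of the one-fast/two-slow
analysis.

## Synthetic traces

`synth.make_trace` builds piecewise traces with exactly known ground truth:
a silent phase at a hyperpolarized baseline, an active phase at a
depolarized plateau carrying `n_spikes` evenly spaced raised-cosine bumps
(width = active duration / (2·n_spikes), so each spike's prominence is
exactly its amplitude), seeded Gaussian noise, and a triangular Ca²⁺
surrogate with its minimum at the period boundary. Defaults (period 4 s,
active fraction 0.5, plateau −25 mV, baseline −65 mV, spike amplitude 8 mV,
noise 0.1 mV) imitate the scale of a pseudo-plateau burst. What these
fixtures do **not** emulate: the decaying-then-growing rotation envelope,
amplitude drift, baseline wander, or band-limited recording noise — so
passing the recovery tests shows the detector reads off a known burst
geometry correctly, not that it is robust to every pathology of real
recordings.

## Numerical choices and degenerate cases

* Exponential arguments are clamped at ±500 (saturation is exact far
  outside the physiological range; this only prevents overflow).
* Parameters are a frozen dataclass; scans operate on modified copies.
* A pair of folded-singularity roots closer than 1e-8 μM is merged and
  flagged `degenerate`.
* `n_of` raises at `V = VK` (the manifold graph is singular there);
  projections raise a dedicated error when no root exists on the target
  sheet, which callers treat as "the orbit left the fold regime".
* Bifurcation bisections refine to 1e-6 nS (1e-4 nS for the δ = 0 curve,
  each evaluation of which costs a full singular-orbit construction).
* Fold-hit events use the solver's root-finding on `V − V_fold` (LSODA
  event tolerance), i.e. well below 1e-7 mV.

## Known limitations

* The twisted slow-manifold surfaces and explicit secondary canards are
  not computed; rotation counts are exercised only via `s_max` and via
  spike counting in simulations.
* The full-system period-doubling curve is not continued; the
  spiking/bursting border is located empirically by regime classification,
  and the bistable band between the Hopf curve and that border means
  border positions depend slightly on the initial state used.
* At `Cm = 0.001` pF a sub-percent fraction of slow-phase samples falls
  outside the 1 mV × 0.01 μM tube around the singular orbit at `gK = 4`:
  the finite-`Cm` canard delay shifts the jump at the folded node by
  ~0.014 μM. This is a property of the perturbation, not a solver error.
* Hopf criticality labels from the probing heuristic agree with normal-form
  analysis only when the distant attractor is genuinely distant (>10 mV);
  near a saddle-node of periodics the label follows the stable cycle.
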