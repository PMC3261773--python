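# lactoburst

Slow–fast (canard) analysis of pseudo-plateau bursting in a pituitary
lactotroph model.

Lactotrophs and other anterior-pituitary cells fire *pseudo-plateau
bursts*: a depolarized plateau carrying small spikes, alternating with
hyperpolarized silent phases. The classical two-fast/one-slow bursting
analysis explains little here. This package implements the
one-fast/two-slow alternative for the standard three-variable lactotroph
model

```
Cm dV/dt = −(I_Ca + I_K + I_KCa + I_BK),   dn/dt = (n∞(V) − n)/τn,
dc/dt = −fc (α I_Ca + kc c),
```

in which the bursts are canard-induced mixed-mode oscillations organised by
a **folded node** of the desingularized reduced flow on the critical
manifold `f(V, c, n) = 0`. The package computes, from the ODEs alone:

* the critical manifold, its fold curves L± and their projections;
* the desingularized flow, its ordinary and folded singularities, the
  folded-node eigenvalue ratio `μ = λ₁/λ₂` and the rotation bound
  `S_max = ⌊(μ+1)/(2μ)⌋`;
* singular periodic orbits with the strong canard and the signed funnel
  distance `δ` (δ > 0 ⇒ funnel entry ⇒ bursting; δ < 0 ⇒ spiking);
* one- and two-parameter bifurcation maps in `(g_K, g_BK)`: transcritical
  (type II folded saddle-node), type I folded saddle-nodes, focus↔node
  transitions, the fold-merge line and its codimension-2 endpoint, and the
  δ = 0 curve bounding the bursting region;
* full-system simulations with burst-feature extraction (regime, period,
  active-phase duration, spikes per burst) and full-system Hopf detection;
* the comparison two-fast/one-slow "z-curve" analysis.

It is intended for researchers in computational neuroendocrinology and
slow–fast dynamics who want these diagnostics reproducible and tested
rather than assembled by hand in XPPAUT/AUTO sessions.

## Worked example

```python
>>> from lactoburst import (ModelParams, find_TR, find_SN,
...                         find_folded_singularities, singular_orbit_delta)
>>> p = ModelParams()            # default lactotroph, gK = 4, gBK = 0.4 nS
>>> [f"{s.classification} at c={s.c:.3f}" for s in
...  find_folded_singularities(p) if s.on_curve == "L_plus" and s.c > 0]
['folded_node at c=0.304']
>>> find_TR(p, "gK", (0.1, 1.0)).gK      # depolarized-steady border
0.5130820913854433
>>> find_SN(p, "gK", (4.0, 10.0)).gK     # folded node disappears
7.588904694854358
>>> singular_orbit_delta(p)              # funnel entry: bursting predicted
0.013504175726856804
>>> singular_orbit_delta(p.replace(gK=5.1))   # outside funnel: spiking
-0.004339036237701682
```

The folded-node window in `g_K` at `g_BK = 0.4` nS runs from the
transcritical point 0.5131 nS to the folded saddle-node 7.589 nS; inside
it, the singular orbit enters the funnel (δ = +0.0135 μM) at `g_K = 4`
(the cell bursts) and misses it (δ = −0.0043 μM) at `g_K = 5.1` (the cell
spikes). Simulating the full system confirms the prediction:

```python
>>> from lactoburst import simulate, extract_features
>>> bf = extract_features(simulate(p.replace(gK=6.0, gBK=1.0, Cm=5.0)))
>>> bf.regime, bf.spikes_per_burst
('bursting', 3)
```

The same machinery is available from the shell:

```sh
lactoburst scan1d --kind TR --param gK --bracket 0.1,1.0 --out-dir out/
lactoburst singularities --gK 4 --gBK 0.4 --out-dir out/
lactoburst simulate --gK 6 --gBK 1 --Cm 5 --out-dir out/
```

Each command writes CSV/JSON plus the fully resolved configuration.

## Layout

| module | contents |
| --- | --- |
| `params` | immutable Table-of-constants parameter set, JSON/TOML I/O |
| `model` | currents, activation curves, full RHS, analytic 3×3 Jacobian |
| `manifold` | critical manifold, fold voltages, projections P(L±) |
| `desing` | desingularized flow, ordinary/folded singularities, μ, S_max |
| `orbit` | singular periodic orbits, strong canard, funnel distance δ |
| `bifurcation` | TR/SN/focus–node/fold-merge/δ = 0 detection, region map |
| `simulate` | stiff integration, burst features, feature maps, Hopf slices |
| `zcurve` | two-fast/one-slow comparison analysis |
| `synth` | synthetic burst traces with known ground truth |
| `cli`, `config` | `lactoburst` command-line tool and run configuration |

See `docs/methods.md` for the numerical methods and design decisions.
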