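"""Synthetic voltage traces with known burst structure.

Feature extraction must be testable independently of the ODE solver, so
this module builds piecewise traces with exactly known period, active-phase
duration and spike count: a silent phase at a hyperpolarized baseline, an
active phase at a depolarized plateau carrying evenly spaced raised-cosine
spikes, plus seeded Gaussian noise.  The raised-cosine shape makes each
spike's prominence exactly its amplitude, so detector thresholds are
exercised deliberately.  A matching triangular Ca2+ waveform (minimum at
the period boundary) drives the period detector the same way the slow
variable does in simulated traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams
from .simulate import Trace

__all__ = ["SyntheticTraceSpec", "make_trace"]


@dataclass(frozen=True)
class SyntheticTraceSpec:
    period: float = 4000.0        # ms
    active_fraction: float = 0.5  # of the period
    n_spikes: int = 3
    baseline_V: float = -65.0     # mV, silent phase
    plateau_V: float = -25.0      # mV, active phase
    spike_amplitude: float = 8.0  # mV
    noise_sd: float = 0.1         # mV
    n_periods: int = 6
    dt: float = 0.5               # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period <= 0 or self.dt <= 0:
            raise ValueError("period and dt must be > 0")
        if not 0.0 < self.active_fraction < 1.0:
            raise ValueError("active_fraction must lie in (0, 1)")
        if self.n_spikes < 0 or self.n_periods < 1:
            raise ValueError("n_spikes >= 0 and n_periods >= 1 required")


def make_trace(spec: SyntheticTraceSpec) -> Trace:
    """Deterministic synthetic trace for a given spec (fixed seed).

    The active phase opens each period.  Spikes are raised-cosine bumps of
    width active_duration / (2 n_spikes), centered at evenly spaced points
    of the active phase.
    """
    t = np.arange(0.0, spec.n_periods * spec.period, spec.dt)
    phase = np.mod(t, spec.period)
    active = spec.active_fraction * spec.period
    in_active = phase < active

    V = np.where(in_active, spec.plateau_V, spec.baseline_V).astype(float)
    if spec.n_spikes > 0:
        width = active / (2.0 * spec.n_spikes)
        centers = (np.arange(spec.n_spikes) + 0.5) * active / spec.n_spikes
        for ctr in centers:
            d = phase - ctr
            mask = in_active & (np.abs(d) < width / 2.0)
            V[mask] += spec.spike_amplitude * 0.5 * (
                1.0 + np.cos(2.0 * np.pi * d[mask] / width))

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        V = V + rng.normal(0.0, spec.noise_sd, size=V.shape)

    # triangular Ca2+ surrogate: rises during the active phase, decays
    # during the silent phase, minimum at the period boundary
    c = np.where(in_active, 0.2 + 0.2 * phase / active,
                 0.4 - 0.2 * (phase - active) / (spec.period - active))
    n = np.full_like(V, 0.1)
    return Trace(t, V, n, c, ModelParams(),
                 meta={"synthetic": True, "spec": spec})
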