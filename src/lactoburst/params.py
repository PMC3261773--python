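"""Model parameters for the lactotroph conductance-based model.

Units are fixed throughout the package: mV, ms, pF, nS, pA, uM.  With these
units nS*mV = pA and pF/nS = ms, so no hidden conversion factors appear in
the equations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

__all__ = ["ModelParams", "load_params", "save_params", "PARAM_KEYS"]

# Canonical key order used for config files and CSV headers.
PARAM_KEYS = (
    "Cm", "gCa", "gK", "gKCa", "gBK", "VCa", "VK",
    "vm", "sm", "vn", "sn", "taun", "Kd", "vb", "sb",
    "fc", "alpha", "kc",
)


@dataclass(frozen=True)
class ModelParams:
    """Immutable parameter set for the lactotroph model.

    Defaults are the standard values for the pituitary lactotroph cell
    (pseudo-plateau burster).  Instances are frozen; parameter scans create
    modified copies via :meth:`replace`, which prevents aliasing bugs when a
    grid of parameter sets is built.

    Attributes
    ----------
    Cm : float
        Membrane capacitance (pF).  Acts as the singular perturbation
        parameter: the voltage time scale shrinks with ``Cm``.
    gCa, gK, gKCa, gBK : float
        Maximal conductances (nS) of the Ca2+ current, delayed-rectifier K+
        current, SK (Ca2+-activated K+) current and BK current.
    VCa, VK : float
        Reversal potentials (mV).
    vm, sm, vn, sn, vb, sb : float
        Midpoints and slopes (mV) of the Boltzmann activation curves for the
        Ca2+ channel (m), delayed rectifier (n) and BK channel (b).
    taun : float
        Activation time constant of n (ms).
    Kd : float
        Ca2+ concentration of half-maximal SK activation (uM).
    fc : float
        Fraction of cytosolic Ca2+ that is free (dimensionless).
    alpha : float
        Conversion factor from charge to concentration (uM/fC).
    kc : float
        Ca2+ extrusion rate (1/ms).
    """

    Cm: float = 5.0
    gCa: float = 2.0
    gK: float = 4.0
    gKCa: float = 1.7
    gBK: float = 0.4
    VCa: float = 50.0
    VK: float = -75.0
    vm: float = -20.0
    sm: float = 12.0
    vn: float = -5.0
    sn: float = 10.0
    taun: float = 43.0
    Kd: float = 0.5
    vb: float = -20.0
    sb: float = 5.6
    fc: float = 0.01
    alpha: float = 0.0015
    kc: float = 0.16

    def __post_init__(self) -> None:
        for name in ("gCa", "gK", "gKCa", "gBK"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        for name in ("sm", "sn", "sb", "taun", "Kd", "kc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.fc <= 1.0:
            raise ValueError("fc must lie in (0, 1]")

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields changed."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_KEYS}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        unknown = set(d) - set(PARAM_KEYS)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


def load_params(path: str | Path) -> ModelParams:
    """Read a parameter set from a flat JSON or TOML key-value file."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    return ModelParams.from_dict(data)


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a parameter set as flat JSON (keys in canonical order)."""
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=1)
        fh.write("\n")
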