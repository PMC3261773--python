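"""Run configuration shared by the CLI subcommands.

A run is described by a flat JSON or TOML file with three groups: model
parameter overrides (Table-style symbols, e.g. ``gK``), solver settings and
feature-extraction thresholds.  Unknown keys are rejected, and every CLI
run writes the fully-resolved configuration next to its outputs so results
are reproducible from the output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .params import PARAM_KEYS, ModelParams
from .simulate import FeatureConfig

__all__ = ["RunConfig", "load_config"]

_SOLVER_KEYS = ("t_end", "transient", "dt", "rtol", "atol")
_FEATURE_KEYS = tuple(f.name for f in dataclasses.fields(FeatureConfig))


@dataclass
class RunConfig:
    params: ModelParams = field(default_factory=ModelParams)
    t_end: float = 60000.0      # ms
    transient: float = 20000.0  # ms
    dt: float = 0.5             # ms
    rtol: float = 1e-8
    atol: float = 1e-10
    features: FeatureConfig = field(default_factory=FeatureConfig)

    def resolved(self) -> dict:
        out = dict(self.params.to_dict())
        for k in _SOLVER_KEYS:
            out[k] = getattr(self, k)
        for k in _FEATURE_KEYS:
            out[k] = getattr(self.features, k)
        return out

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.resolved(), fh, indent=1)
            fh.write("\n")


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional file plus CLI overrides.

    Later sources win.  Unknown keys raise ``KeyError``.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                data.update(tomllib.load(fh))
        else:
            with open(path) as fh:
                data.update(json.load(fh))
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(data) - set(PARAM_KEYS) - set(_SOLVER_KEYS) - set(_FEATURE_KEYS)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")

    cfg = RunConfig()
    pdict = {k: float(v) for k, v in data.items() if k in PARAM_KEYS}
    if pdict:
        cfg.params = ModelParams.from_dict({**cfg.params.to_dict(), **pdict})
    for k in _SOLVER_KEYS:
        if k in data:
            setattr(cfg, k, float(data[k]))
    fdict = {}
    for k in _FEATURE_KEYS:
        if k in data:
            fdict[k] = int(data[k]) if k == "min_periods" else float(data[k])
    if fdict:
        cfg.features = dataclasses.replace(cfg.features, **fdict)
    return cfg
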