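"""Run configuration from YAML or JSON files.

A config file either names a scenario preset (with optional overrides) or
spells out simulation parameters directly:

.. code-block:: yaml

    scenario: "High ep."
    seed: 7
    scale: 20
    genome_shrink: 100
    overrides:
      sample_size: 25
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .params import SimParams, scenario_params

__all__ = ["params_from_config"]


def params_from_config(path) -> SimParams:
    """Build :class:`SimParams` from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must contain a mapping")

    cfg = dict(cfg)
    scale = int(cfg.pop("scale", 1))
    shrink = int(cfg.pop("genome_shrink", 1))
    overrides = dict(cfg.pop("overrides", {}))
    seed = cfg.pop("seed", None)

    if "scenario" in cfg:
        name = cfg.pop("scenario")
        if cfg:
            raise ValueError(f"unexpected config keys alongside 'scenario': {sorted(cfg)}")
        params = scenario_params(name, seed=seed, **overrides)
    else:
        cfg.update(overrides)
        if seed is not None:
            cfg["seed"] = seed
        if "sample_generations" in cfg:
            cfg["sample_generations"] = tuple(cfg["sample_generations"])
        params = SimParams(**cfg)
    if scale > 1 or shrink > 1:
        params = params.scaled(scale, shrink)
    return params
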