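"""Configuration files, run manifests and deterministic seed spawning.

Config files are flat YAML key–value mappings.  Keys mirror
:class:`~softcells.params.SimParams` directly; radius-distribution keys
carry the prefix ``radius_`` (e.g. ``radius_kind``,
``radius_mean_radius``).  Unknown keys are rejected.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, fields, asdict
from typing import Optional

import numpy as np
import yaml

from .params import RadiusDistributionSpec, SimParams

__all__ = [
    "load_config",
    "save_config",
    "config_to_objects",
    "objects_to_config",
    "spawn_seeds",
    "RunManifest",
]

_RADIUS_PREFIX = "radius_"


def objects_to_config(
    params: SimParams, spec: RadiusDistributionSpec
) -> dict:
    cfg = params.to_dict()
    for key, val in spec.to_dict().items():
        cfg[_RADIUS_PREFIX + key] = val
    return cfg


def config_to_objects(cfg: dict) -> tuple[SimParams, RadiusDistributionSpec]:
    sim_keys = {f.name for f in fields(SimParams)}
    spec_keys = {f.name for f in fields(RadiusDistributionSpec)}
    sim_d, spec_d = {}, {}
    for key, val in cfg.items():
        if key.startswith(_RADIUS_PREFIX) and key[len(_RADIUS_PREFIX):] in spec_keys:
            spec_d[key[len(_RADIUS_PREFIX):]] = val
        elif key in sim_keys:
            sim_d[key] = val
        else:
            raise KeyError(f"unknown configuration key {key!r}")
    return SimParams(**sim_d), RadiusDistributionSpec(**spec_d)


def load_config(path: str) -> tuple[SimParams, RadiusDistributionSpec]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a flat mapping")
    return config_to_objects(cfg)


def save_config(
    path: str, params: SimParams, spec: RadiusDistributionSpec
) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(objects_to_config(params, spec), fh, sort_keys=True)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """n independent child seeds from a master seed (counter-based
    SeedSequence spawning); each child is a plain 31-bit integer so it
    can be recorded in a manifest and reused directly."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


@dataclass
class RunManifest:
    """Reproducibility record for a run or sweep: the full configuration
    snapshot, every derived seed, and the produced outputs."""

    config: dict
    master_seed: int
    child_seeds: list = field(default_factory=list)
    software_version: str = ""
    outputs: list = field(default_factory=list)
    wall_times_s: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    created: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S")
    )

    def record_output(self, label: str, path: str) -> None:
        self.outputs.append({"label": label, "path": path})

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
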