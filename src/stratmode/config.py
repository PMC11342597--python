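"""Run configuration: defaults, YAML loading, and strict validation.

A run configuration bundles every knob of the pipeline — sea-level forcing,
platform geometry, the simulated mode of evolution, the sampling scheme and
the fitting options — under one root seed. Defaults are the study conditions:
1 kyr steps, 70 m/Myr subsidence, one sample per metre with 100 specimens of
within-sample variance 0.1, joint-likelihood fits with variance pooling.

Unknown keys anywhere in the document are rejected by name, so a typo never
silently falls back to a default.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig", "DEFAULTS", "load_config", "write_config"]

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "stratmode_out",
    "sea_level": {
        "kind": "sinusoidal",  # sinusoidal | glacioeustatic | file
        "components": [[20.0, 1.0, 0.0], [2.0, 0.112, 0.0]],
        "duration": 2.0,
        "dt": 0.001,
        "path": None,  # for kind = file
        "age_unit": "myr",
        "normalize": True,
    },
    "platform": {
        "duration": 2.0,
        "dt": 0.001,
        "n_strike": 10,
        "n_dip": 150,
        "cell_size": 100.0,
        "subsidence": 70.0,
        "depth_gradient": 80.0 / 15.0,
        "transport_fraction": 0.3,
        "recolonization_lag": 0,
        "neighbor_rule": None,
    },
    "evolution": {
        "mode": "drift",  # stasis | bm | drift
        "mu": 5.0,
        "sigma": 1.0,
        "m": 0.0,
        "s": 1.0,
    },
    "sampling": {
        "spacing": 1.0,
        "n_specimens": 100,
        "within_var": 0.1,
    },
    "fitting": {
        "method": "joint",  # joint | ad
        "pool": True,
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (nested dictionaries with defaults filled)."""

    seed: int
    outdir: str
    sea_level: dict
    platform: dict
    evolution: dict
    sampling: dict
    fitting: dict

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "sea_level": copy.deepcopy(self.sea_level),
            "platform": copy.deepcopy(self.platform),
            "evolution": copy.deepcopy(self.evolution),
            "sampling": copy.deepcopy(self.sampling),
            "fitting": copy.deepcopy(self.fitting),
        }


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {where!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = copy.deepcopy(value)
    return out


def from_dict(document: dict | None) -> RunConfig:
    merged = _merge(DEFAULTS, document or {})
    if merged["evolution"]["mode"] not in ("stasis", "bm", "drift"):
        raise ValueError("evolution.mode must be stasis, bm or drift")
    if merged["fitting"]["method"] not in ("joint", "ad"):
        raise ValueError("fitting.method must be joint or ad")
    return RunConfig(
        seed=int(merged["seed"]),
        outdir=str(merged["outdir"]),
        sea_level=merged["sea_level"],
        platform=merged["platform"],
        evolution=merged["evolution"],
        sampling=merged["sampling"],
        fitting=merged["fitting"],
    )


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON) configuration file, filling defaults."""
    with open(path) as fh:
        document = yaml.safe_load(fh)
    if document is None:
        document = {}
    if not isinstance(document, dict):
        raise ValueError("configuration must be a mapping")
    return from_dict(document)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def config_json(config: RunConfig) -> str:
    return json.dumps(config.to_dict(), indent=2)
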