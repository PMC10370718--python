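"""Layered run configuration: defaults < config file < command-line flags.

Every consumed key has a documented default below; keys found in a config
file that are not known raise a warning (never a silent ignore).  Each key
remembers where its value came from (``default`` / ``file`` / ``flag``) so a
run manifest can record full provenance.
"""

from __future__ import annotations

import copy
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

#: Documented defaults for every configuration key.
DEFAULTS: dict = {
    "frontend": {
        "n_fft": 1024,
        "hop": 256,
        "n_mels": 128,
        "highpass_bins": 20,
        "log_scale": True,
    },
    "model": {
        "depth": 4,
        "base_filters": 32,
        "kernel_size": 3,
        "n_classes": 3,
        "binary_mode": False,
        "use_batchnorm": False,
        "two_dimensional": False,
    },
    "training": {
        "epochs": 100,
        "learning_rate": 1e-3,
        "val_fraction": 0.12,
        "seed": 0,
    },
    "ensemble": {
        "strategy": "random_init",
        "n_members": 10,
        "tile_len": 1024,
        "tile_overlap": 128,
    },
    "hmm": {
        "template": "beetle",  # beetle | binary | section with explicit tables
        "enabled": True,
    },
    "metrics": {
        "min_event_frames": 10,
        "background_class": "X",
        "min_overlap": 0.5,
    },
    "classes": ["A", "B", "X"],
    "scene": {
        "duration_s": 60.0,
        "sample_rate": 48000,
        "events_per_class": 20,
        "run_structure": True,
        "background_level": 0.01,
    },
    "annotations": {
        "annotation_col": "Annotation",
        "context_frames": 8,
        "background_ratio": 1.0,
    },
}


@dataclass
class RunConfig:
    """Merged key-value tree with per-key provenance."""

    values: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))
    provenance: dict = field(default_factory=dict)

    def get(self, dotted: str):
        node = self.values
        for part in dotted.split("."):
            if not isinstance(node, dict) or part not in node:
                raise ConfigError(f"unknown configuration key: {dotted!r}")
            node = node[part]
        return node

    def set(self, dotted: str, value, source: str) -> None:
        parts = dotted.split(".")
        node = self.values
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
        self.provenance[dotted] = source

    def source_of(self, dotted: str) -> str:
        return self.provenance.get(dotted, "default")

    def snapshot(self) -> dict:
        return {
            "values": copy.deepcopy(self.values),
            "provenance": dict(self.provenance),
        }


def _merge(cfg: RunConfig, tree: dict, source: str, prefix: str = "") -> None:
    for key, value in tree.items():
        dotted = f"{prefix}{key}"
        known = True
        node = DEFAULTS
        for part in dotted.split("."):
            if isinstance(node, dict) and part in node:
                node = node[part]
            else:
                known = False
                break
        if not known:
            warnings.warn(f"unknown configuration key ignored downstream: {dotted!r}")
        if isinstance(value, dict) and isinstance(node, dict):
            _merge(cfg, value, source, prefix=f"{dotted}.")
        else:
            cfg.set(dotted, value, source)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file and flag overrides.

    ``overrides`` maps dotted keys to values and always wins over the file.
    """
    cfg = RunConfig()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            tree = yaml.safe_load(fh) or {}
        if not isinstance(tree, dict):
            raise ConfigError(f"config file must be a mapping: {path}")
        _merge(cfg, tree, "file")
    for dotted, value in (overrides or {}).items():
        if value is not None:
            cfg.set(dotted, value, "flag")
    return cfg


def write_manifest(cfg: RunConfig, out_dir, command: str, seeds: dict, artifacts: dict) -> Path:
    """Write a machine-readable run manifest (config snapshot + seeds).

    The snapshot is sufficient to reproduce the run bit for bit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": cfg.snapshot(),
        "seeds": seeds,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    path = out_dir / f"{command.replace(' ', '_')}_manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return path
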