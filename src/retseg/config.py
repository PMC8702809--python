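"""YAML configuration: one document covering all pipeline namespaces.

Unknown keys are rejected so typos fail loudly instead of silently falling
back to defaults.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULTS: dict = {
    "preprocess": {
        "gaussian": {"kernel": 3, "sigma": 1.0},
        "gamma": 1.3,
        "levels": 256,
    },
    "patch": {"window": 64, "step": 16},
    "augment": {"flip": True, "rot90": True, "crop_min_frac": 0.8, "seed": 0},
    "model": {
        "in_channels": 1,
        "stage_channels": [64, 128, 256],
        "aspp_rates": [1, 2, 3, 4],
        "aspp_kernels_per_branch": 128,
        "dropout_rate": 0.2,
        "l2_coeff": 1.0e-4,
        "n_supervision": 3,
        "window": 64,
        "attention_stage": 1,
        "aspp_stage": 2,
    },
    "train": {
        "batch_size": 20,
        "epochs": 500,
        "learning_rate": 0.001,
        "optimizer": "adam",
        "seed": 0,
        "augment": True,
        "loss_mode": "default",  # or "beta-all"
        "val_fraction": 0.1,
    },
    "eval": {"threshold": 0.5, "fov_only": True},
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for k, v in override.items():
        where = f"{path}.{k}" if path else k
        if k not in defaults:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(defaults[k], dict):
            if not isinstance(v, dict):
                raise ConfigError(f"{where} must be a mapping")
            out[k] = _merge(defaults[k], v, where)
        else:
            out[k] = v
    return out


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config merged over the defaults; unknown keys raise."""
    if path is None:
        return default_config()
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    return _merge(DEFAULTS, doc)
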