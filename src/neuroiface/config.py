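"""Experiment configuration: YAML loading, defaults, validation, hashing.

A configuration is a nested mapping with named sections.  Loading fills in
defaults, rejects unknown keys with their dotted location, and computes a
content hash sufficient to re-run bit-comparably.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "artifacts",
    "data": {
        "source": "synthetic",       # "synthetic" | "files"
        "n_classes": 10,
        "n_per_class": 200,
        "image_size": [32, 32],
        "images_path": None,
        "recordings_path": None,
        "region_name": None,
        # synthetic-region settings
        "source_layer": None,        # default: last injectable layer
        "n_features": 64,
        "noise_sd": 0.0,
    },
    "network": {
        "preset": None,              # null | "vgg-miniature"
        "blocks": [[16], [32], [64], [64]],
        "use_batch_norm": True,
        "dense": [64],
        "dropout": 0.4,
        "weight_decay": 5e-4,
        "input_size": [32, 32, 3],
        "checkpoint": None,
        "training": {
            "batch_size": 64,
            "learning_rate": 1e-3,
            "momentum": 0.90561,
            "max_epochs": 60,
            "lr_patience": 4,
            "lr_factor": 0.5,
            "stop_patience": 10,
            "val_fraction": 0.1,
            "augment": True,
        },
    },
    "translation": {
        "mode": "mse",               # "mse" | "end_to_end" | "pca_target"
        "solver": "ridge",           # "ridge" | "sgd" | "adadelta"
        "l2": 3e-4,
        "learning_rate": 0.1,
        "batch_size": 64,
        "momentum": 0.9,
        "pca_rank": None,
        "convention": "zscore",
    },
    "evaluation": {
        "layers": None,              # null = all injectable layers
        "cv_scheme": "stratified_kfold",
        "k": 8,
        "kl_reverse": False,
    },
    "granger": {
        "p_max": 4,
        "criterion": "bic",
        "alpha": 0.05,
        "layer": None,
        "d_v4": 48,
        "d_it": 48,
        "n_trials_per_class": 20,
        "dynamics": {
            "t_bins": 45,
            "stimulus_on": 2,
            "stimulus_off": 12,
            "feedforward_lag": 2,
            "feedback_lag": 3,
            "class_gain_it": 1.0,
            "class_gain_feedback": 0.8,
            "stimulus_gain": 1.0,
            "noise_sd": 0.3,
        },
    },
    "perturbation": {
        "gamma": 4.0,
        "n_repeats": 8,
        "metric": "nmad",
        "reference_layer": None,     # null = last conv layer
    },
    "baselines": {
        "n_pcs": 200,
        "n_pls": 10,
        "pixel_components": 256,
        # the sparse many-class MVPA regime (2 examples per class)
        "mvpa_n_classes": 144,
        "mvpa_train_per_class": 40,
        "mvpa_n_per_class": 2,
        "mvpa_noise_sd": 5.5,
    },
}


@dataclass
class ExperimentConfig:
    """Validated configuration with defaults materialized."""

    values: dict
    content_hash: str
    path: str | None = None

    def __getitem__(self, key: str):
        return self.values[key]

    def section(self, name: str) -> dict:
        return self.values[name]


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, given: dict, location: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in given.items():
        where = f"{location}.{key}" if location else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {where!r}")
        if isinstance(defaults[key], dict) and defaults[key]:
            if not isinstance(value, dict):
                raise ConfigError(f"section {where!r} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


def config_hash(values: dict) -> str:
    canon = json.dumps(values, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def make_config(overrides: dict | None = None) -> ExperimentConfig:
    values = _merge(DEFAULTS, overrides or {})
    return ExperimentConfig(values, config_hash(values))


def load_config(path: str | Path) -> ExperimentConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    cfg = make_config(raw)
    cfg.path = str(path)
    return cfg
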