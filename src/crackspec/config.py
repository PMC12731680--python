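"""Run configuration: nested defaults, strict validation, YAML loading."""

from __future__ import annotations

import copy

import yaml

from .errors import ConfigError
from .io_envi import load_yaml_config

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "runs",
    "log_level": "INFO",
    "calib": {"epsilon": 1e-6, "clamp_max": 2.0},
    "sg": {"window": 11, "polyorder": 2},
    "msc": {"enabled": True},
    "simulate": {
        "n_eggs": 20, "rows": 64, "cols": 64, "n_bands": 273,
        "spot_density": 3.0, "noise_sd": 0.02, "background_level": 0.05,
    },
    "select": {
        "method": "cars", "n_latent": 5, "pixels_per_class": 40,
        "cars": {"n_iterations": 50, "sampling_ratio": 0.8, "mc_draws": 30,
                 "min_bands": 2, "max_bands": None},
        "spa": {"max_bands": 20, "mc_draws": 30},
        "rf": {"n_iterations": 800, "temperature_init": 0.05,
               "temperature_decay": 0.95, "threshold": 0.2, "mc_draws": 8},
    },
    "network": {
        "in_bands": 15, "encoder_units": 3, "base_channels": 16,
        "simam_lambda": 1e-4, "attention_variant": "direct", "threshold": 0.5,
    },
    "train": {
        "epochs": 100, "batch_size": 32, "learning_rate": 1e-4,
        "weight_decay": 1e-4, "patience": 15, "focal_gamma": 2.0,
        "focal_alpha": 0.8, "dice_weight": 0.5, "crop_size": 32,
        "max_batches_per_epoch": None, "scheduler_t0": 10,
        "scheduler_t_mult": 2,
    },
}


def validate_config(config: dict, defaults: dict | None = None,
                    path: str = "") -> None:
    """Reject keys that do not exist in the defaults tree."""
    defaults = DEFAULTS if defaults is None else defaults
    for key, value in config.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            validate_config(value, defaults[key], here)


def merge_config(overrides: dict | None) -> dict:
    """Defaults overlaid with (validated) overrides."""
    merged = copy.deepcopy(DEFAULTS)
    if not overrides:
        return merged
    validate_config(overrides)

    def overlay(base, over):
        for k, v in over.items():
            if isinstance(base.get(k), dict) and isinstance(v, dict):
                overlay(base[k], v)
            else:
                base[k] = v

    overlay(merged, overrides)
    return merged


def load_config(path: str | None) -> dict:
    """Load a YAML config file and merge it over the defaults."""
    overrides = load_yaml_config(path) if path else {}
    return merge_config(overrides)


def dump_config(config: dict | None = None) -> str:
    """YAML dump of the fully resolved configuration (for archival)."""
    return yaml.safe_dump(config or copy.deepcopy(DEFAULTS),
                          sort_keys=False, default_flow_style=False)
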