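"""Flat key-value run configuration.

A config file is a flat YAML mapping; command-line flags override file
values, and the effective (merged) configuration is written next to every
run's outputs so each result is reproducible from its own directory.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .observer import ObserverParams, ResponseMapping
from .prior import PriorModel, build_prior

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "merge_config",
    "write_effective_config",
    "prior_from_config",
    "observer_from_config",
    "response_mapping_from_config",
]

DEFAULT_CONFIG = {
    # prior: two-peak von Mises mixture (degrees / plain kappas / weights)
    "peaks_deg": [0.0, 180.0],
    "concentrations": [2.0, 2.0],
    "weights": [0.5, 0.5],
    # observer
    "kappa": 4.0,
    # perception-action scaling per condition label
    "alphas": {
        "line80": 0.85,
        "arc80": 0.85,
        "arc160": 1.0,
        "arc240": 1.15,
        "circle360": 1.0,
    },
    # numerics / bookkeeping
    "grid_resolution": 1024,
    "fit_grid_resolution": 512,
    "seed": 0,
    "experiment": "exp3",
    "n_participants": None,
    "exp3_reps_per_heading": 15,
    "participant_heterogeneity": 0.3,
    "n_restarts": 5,
    "constrain_circle_alpha": False,
    "log_level": "INFO",
}


def load_config(path) -> dict:
    """Load a flat YAML config, rejecting unknown keys by name."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must be a flat key-value mapping")
    unknown = sorted(set(data) - set(DEFAULT_CONFIG))
    if unknown:
        raise ValueError(
            f"unknown config keys in {path}: {unknown}; "
            f"valid keys are {sorted(DEFAULT_CONFIG)}"
        )
    return data


def merge_config(*layers: dict) -> dict:
    """Defaults first, then file values, then flag overrides; later wins.

    ``None`` values in an override layer mean "not set" and are skipped.
    """
    merged = dict(DEFAULT_CONFIG)
    for layer in layers:
        for key, value in (layer or {}).items():
            if key not in DEFAULT_CONFIG:
                raise ValueError(f"unknown config key {key!r}")
            if value is None:
                continue
            if key == "alphas" and isinstance(value, dict):
                alphas = dict(merged["alphas"])
                alphas.update(value)
                merged["alphas"] = alphas
            else:
                merged[key] = value
    return merged


def write_effective_config(config: dict, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "effective_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path


def prior_from_config(config: dict) -> PriorModel:
    return build_prior(
        peaks_deg=config["peaks_deg"],
        concentrations=config["concentrations"],
        weights=config["weights"],
        resolution=int(config["grid_resolution"]),
    )


def observer_from_config(config: dict) -> ObserverParams:
    return ObserverParams(float(config["kappa"]))


def response_mapping_from_config(config: dict) -> ResponseMapping:
    return ResponseMapping({k: float(v) for k, v in config["alphas"].items()})
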