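"""Run configuration: one structured YAML file with per-stage blocks.

A single master seed at the top level feeds every stage through named
substreams, so the whole pipeline is reproducible from the one file.  All
keys are validated against the canonical defaults before any compute
starts; unknown keys are rejected.
"""

from __future__ import annotations

import copy

import numpy as np
import yaml

from .dynamics import TrajectoryConfig
from .errors import ConfigurationError
from .model_systems import ModelSpec, build_model
from .surrogate import TrainConfig, UncertaintyThresholds

DEFAULTS: dict = {
    "seed": 1,
    "model": {
        "model_id": "ladder",
        "parameters": {},
    },
    "sampling": {
        "n_samples": 20,
        "remove_rotation": False,
    },
    "training": {
        "n_wigner": 20,
        "n_path": 39,
        "n_seed_trajectories": 0,
        "seed_max_time_fs": 300.0,
        "seed_stride": 25,
        "epochs": 400,
        "batch_size": 64,
        "learning_rate": 1.0e-3,
        "learning_rate_final": 1.0e-4,
        "split_fraction": 0.9,
        "w_energy": 1.0,
        "w_grad": 1.0,
        "hidden": [64, 64],
        "n_members": 2,
        "thresholds": {
            "energy": 0.05,
            "gradient": 0.25,
            "soc_norm": 60.0,
        },
    },
    "adaptive": {
        "rounds": 4,
        "n_trajectories": 8,
        "max_time_fs": 300.0,
    },
    "dynamics": {
        "provider": "oracle",
        "n_trajectories": 30,
        "max_time_fs": 400.0,
        "nuclear_dt_fs": 0.5,
        "electronic_substeps": 20,
        "gap_gate_ev": 0.5,
        "hops_enabled": True,
        "initial_state": "S1",
        "drift_bound_ev": 0.5,
        "drift_action": "flag",
    },
    "analysis": {
        "open_threshold": 2.2,
        "donor_states": ["S0", "S1"],
        "fit_window_fs": None,
        "log_scale_fit": False,
        "include_early_stopped": False,
    },
}

# model.parameters is an open dict validated by the model itself
_OPEN_BLOCKS = {("model", "parameters")}


def _validate(block, defaults, path=()):
    if not isinstance(block, dict):
        raise ConfigurationError(
            f"config section {'.'.join(path) or '<root>'} must be a mapping"
        )
    unknown = set(block) - set(defaults)
    if unknown:
        raise ConfigurationError(
            f"unknown config keys in {'.'.join(path) or '<root>'}: "
            f"{sorted(unknown)}"
        )
    merged = copy.deepcopy(defaults)
    for k, v in block.items():
        sub_path = path + (k,)
        if isinstance(defaults[k], dict) and sub_path not in _OPEN_BLOCKS:
            merged[k] = _validate(v, defaults[k], sub_path)
        else:
            merged[k] = copy.deepcopy(v)
    return merged


def load_config(path=None, overrides=None) -> dict:
    """Load, validate, and default-fill a run configuration.

    `overrides` is a mapping of dotted keys (e.g. "dynamics.max_time_fs")
    applied after the file, mirroring command-line flags.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = _validate(raw, DEFAULTS)
    for dotted, value in (overrides or {}).items():
        parts = dotted.split(".")
        node = cfg
        for p in parts[:-1]:
            if p not in node or not isinstance(node[p], dict):
                raise ConfigurationError(f"unknown config key {dotted!r}")
            node = node[p]
        if parts[-1] not in node:
            raise ConfigurationError(f"unknown config key {dotted!r}")
        node[parts[-1]] = value
    return cfg


def default_config_yaml() -> str:
    return yaml.safe_dump(DEFAULTS, sort_keys=False)


def config_yaml(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=False)


# ----------------------------------------------------------------------
# derived stage objects

_STAGE_STREAMS = {"sampling": 0, "training": 1, "adaptive": 2,
                  "dynamics": 3, "analysis": 4}


def stage_seed(cfg: dict, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    if stage not in _STAGE_STREAMS:
        raise ConfigurationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(
        entropy=int(cfg["seed"]), spawn_key=(100 + _STAGE_STREAMS[stage],)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def build_model_from_config(cfg: dict):
    m = cfg["model"]
    return build_model(ModelSpec(m["model_id"], dict(m["parameters"])))


def train_config_from_config(cfg: dict) -> TrainConfig:
    t = cfg["training"]
    return TrainConfig(
        split_fraction=t["split_fraction"],
        epochs=t["epochs"],
        batch_size=t["batch_size"],
        learning_rate=t["learning_rate"],
        learning_rate_final=t["learning_rate_final"],
        w_energy=t["w_energy"],
        w_grad=t["w_grad"],
        hidden=tuple(t["hidden"]),
        n_members=t["n_members"],
        seed=stage_seed(cfg, "training"),
    )


def thresholds_from_config(cfg: dict) -> UncertaintyThresholds:
    th = cfg["training"]["thresholds"]
    return UncertaintyThresholds(
        energy=th["energy"], gradient=th["gradient"], soc_norm=th["soc_norm"]
    )


def trajectory_config_from_config(cfg: dict, max_time_fs=None) -> TrajectoryConfig:
    d = cfg["dynamics"]
    return TrajectoryConfig(
        max_time_fs=float(max_time_fs if max_time_fs is not None
                          else d["max_time_fs"]),
        nuclear_dt_fs=d["nuclear_dt_fs"],
        electronic_substeps=d["electronic_substeps"],
        gap_gate_ev=d["gap_gate_ev"],
        hops_enabled=d["hops_enabled"],
        initial_state=d["initial_state"],
        drift_bound_ev=d["drift_bound_ev"],
        drift_action=d["drift_action"],
    )
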