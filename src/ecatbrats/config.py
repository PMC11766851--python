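"""YAML configuration loading for the CLI and scripts."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .model import ModelConfig
from .synthetic import CohortJitter, PhantomSpec
from .training import TrainConfig


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def model_config_from_yaml(path: str | Path) -> ModelConfig:
    return ModelConfig.from_dict(load_yaml(path).get("model", load_yaml(path)))


def train_config_from_yaml(path: str | Path) -> TrainConfig:
    d = load_yaml(path)
    d = d.get("train", d)
    if "betas" in d:
        d["betas"] = tuple(d["betas"])
    return TrainConfig(**d)


def phantom_spec_from_yaml(path: str | Path) -> tuple[PhantomSpec, CohortJitter, int]:
    """Read (base spec, jitter, cohort size) from a synth spec YAML."""
    d = load_yaml(path)
    n = int(d.pop("n", 1))
    jitter = CohortJitter(**{k: tuple(v) if isinstance(v, list) and k != "centre_shift"
                             else v for k, v in d.pop("jitter", {}).items()})
    for key in ("grid_shape", "centre", "radii", "axis_ratios"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if "modality_contrast" in d:
        d["modality_contrast"] = np.asarray(d["modality_contrast"], dtype=float)
    return PhantomSpec(**d), jitter, n


def dump_config(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
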