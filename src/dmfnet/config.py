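"""Structured run configuration (YAML) with strict key validation.

Every CLI run echoes its fully-resolved configuration next to its outputs so
a run is reproducible from the echo plus the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .noise import NoiseSpec
from .training import DEFAULT_LR_SCHEDULE, TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_TOP_KEYS = {"seed", "noise", "train", "paths"}
_NOISE_KEYS = {"mode", "sigma", "sigma_range"}
_TRAIN_KEYS = {"epochs", "batch_size"}


@dataclass
class RunConfig:
    seed: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    epochs: int = 60
    batch_size: int = 32
    paths: dict = field(default_factory=dict)

    def to_train_config(self, checkpoint_dir=None) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr_schedule=DEFAULT_LR_SCHEDULE,
            seed=self.seed,
            noise=self.noise,
            checkpoint_dir=str(checkpoint_dir) if checkpoint_dir else None,
        )


def _reject_unknown(mapping: dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown {context} key(s): {', '.join(sorted(unknown))}")


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration, filling defaults; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) if Path(path).exists() else None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    _reject_unknown(raw, _TOP_KEYS, "config")

    seed = int(raw.get("seed", 0))

    noise_raw = raw.get("noise") or {}
    _reject_unknown(noise_raw, _NOISE_KEYS, "noise")
    mode = noise_raw.get("mode", "blind")
    sigma = float(noise_raw.get("sigma", 25.0))
    if sigma < 0:
        raise ValueError(f"sigma: must be >= 0, got {sigma}")
    sr = noise_raw.get("sigma_range", [0.0, 55.0])
    if len(sr) != 2 or sr[0] < 0 or sr[0] > sr[1]:
        raise ValueError(f"sigma_range: invalid interval {sr}")
    noise = NoiseSpec(mode=mode, sigma=sigma, sigma_range=(float(sr[0]), float(sr[1])))
    noise.validate()

    train_raw = raw.get("train") or {}
    _reject_unknown(train_raw, _TRAIN_KEYS, "train")
    epochs = int(train_raw.get("epochs", 60))
    if epochs < 1:
        raise ValueError(f"epochs: must be >= 1, got {epochs}")
    batch_size = int(train_raw.get("batch_size", 32))
    if batch_size < 1:
        raise ValueError(f"batch_size: must be >= 1, got {batch_size}")

    paths = dict(raw.get("paths") or {})
    return RunConfig(seed=seed, noise=noise, epochs=epochs, batch_size=batch_size, paths=paths)


def save_config(config: RunConfig, path) -> None:
    """Write the fully-resolved configuration as YAML (the run echo)."""
    data = {
        "seed": config.seed,
        "noise": {
            "mode": config.noise.mode,
            "sigma": float(config.noise.sigma),
            "sigma_range": [float(v) for v in config.noise.sigma_range],
        },
        "train": {"epochs": config.epochs, "batch_size": config.batch_size},
        "paths": dict(config.paths),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
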