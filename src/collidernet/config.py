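"""Run configuration: a single YAML file drives every experiment.

Blocks mirror the package modules: ``scm`` (structural-equation
parameters), ``imaging`` (synthetic pool), ``network`` (architecture
and optimizer), ``estimation`` (baseline noise calibration), plus the
global seed, cohort sizes and output directory.  Unknown keys raise a
:class:`ConfigError` listing the offending fields.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .network import ArchitectureSpec, TrainConfig
from .scm import SCMParameters


class ConfigError(ValueError):
    """Invalid or unknown configuration keys."""


@dataclass(frozen=True)
class ImagingConfig:
    n_patches: int = 2000
    size_range_mm2: tuple = (20.0, 2000.0)
    hetero_range: tuple = (0.05, 2.0)
    validation_fraction: float = 0.2335
    pool_seed_offset: int = 3


@dataclass(frozen=True)
class EstimationConfig:
    #: "matching" (oracle floor), "cnn" (ground-truth CNN runs), or explicit sds
    noise_calibration: str = "matching"
    noise_sd_x: float | None = None
    noise_sd_z: float | None = None
    y_from_image: bool = False

    def calibration(self):
        if self.noise_sd_x is not None or self.noise_sd_z is not None:
            if self.noise_sd_x is None or self.noise_sd_z is None:
                raise ConfigError("set both noise_sd_x and noise_sd_z or neither")
            return (self.noise_sd_x, self.noise_sd_z)
        return self.noise_calibration


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/default"
    n_train: int = 3000
    n_val: int = 1000
    replication_seeds: tuple = (0, 1, 2)
    scm: SCMParameters = field(default_factory=SCMParameters)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    arch: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)

    def to_dict(self) -> dict:
        return asdict(self)


def _build(cls, block: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}' block: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' block: {exc}") from exc


_TOP_KEYS = {
    "seed",
    "output_dir",
    "n_train",
    "n_val",
    "replication_seeds",
    "scm",
    "imaging",
    "network",
    "estimation",
}


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    scm = _build(SCMParameters, raw.get("scm", {}) or {}, "scm")
    imaging = _build(ImagingConfig, raw.get("imaging", {}) or {}, "imaging")
    estimation = _build(EstimationConfig, raw.get("estimation", {}) or {}, "estimation")
    network = raw.get("network", {}) or {}
    arch_keys = {f.name for f in fields(ArchitectureSpec)}
    train_keys = {f.name for f in fields(TrainConfig)}
    unknown = set(network) - arch_keys - train_keys
    if unknown:
        raise ConfigError(f"unknown key(s) in 'network' block: {sorted(unknown)}")
    arch = _build(
        ArchitectureSpec, {k: v for k, v in network.items() if k in arch_keys}, "network"
    )
    training = _build(
        TrainConfig, {k: v for k, v in network.items() if k in train_keys}, "network"
    )
    seeds = raw.get("replication_seeds", (0, 1, 2))
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "runs/default")),
        n_train=int(raw.get("n_train", 3000)),
        n_val=int(raw.get("n_val", 1000)),
        replication_seeds=tuple(int(s) for s in seeds),
        scm=scm,
        imaging=imaging,
        arch=arch,
        training=training,
        estimation=estimation,
    )
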