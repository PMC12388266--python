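"""Pipeline configuration: one flat record of every tunable, with defaults.

Config files are YAML mappings (flat or grouped under the field names);
command-line flags override file values, which override the defaults below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # trajectory embedding
    window_length: int = 64
    # STFT stage
    fft_size: int = 256
    hop: int = 64
    mask_method: str = "none"
    mask_floor_quantile: float = 0.10
    mask_gain_floor: float = 0.05
    # DBN
    hidden_dims: tuple = (256, 128, 64)
    pretrain_epochs: int = 10
    finetune_epochs: int = 100
    batch_size: int = 32
    cd_steps: int = 1
    pretrain_rate: float = 1e-3
    lr_schedule: tuple = ((1, 5e-3), (90, 2.5e-3))
    # (pretrain_rate is the plain-SGD CD rate; lr_schedule drives Adam)
    # joint loss
    lambda1: float = 0.7
    lambda2: float = 0.3
    validation_fraction: float = 0.2
    # metrics
    lne_frame_length: int = 100
    weights: tuple = (0.4, 0.3, 0.3)
    # data
    rate: float = 8000.0
    n_training_windows: int = 2048
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.window_length < 1:
            problems.append(f"window_length must be >= 1 "
                            f"(got {self.window_length})")
        if self.fft_size < 2:
            problems.append(f"fft_size must be >= 2 (got {self.fft_size})")
        if not 1 <= self.hop <= self.fft_size:
            problems.append(f"hop must lie in [1, fft_size] (got {self.hop})")
        if self.mask_method not in ("none", "soft_threshold"):
            problems.append(f"mask_method unknown: {self.mask_method!r}")
        if not 0 <= self.mask_floor_quantile < 1:
            problems.append("mask_floor_quantile must lie in [0, 1)")
        if not 0 <= self.mask_gain_floor <= 1:
            problems.append("mask_gain_floor must lie in [0, 1]")
        if len(self.hidden_dims) != 3 or min(self.hidden_dims) < 1:
            problems.append(f"hidden_dims must be three positive widths "
                            f"(got {self.hidden_dims})")
        for name in ("pretrain_epochs", "finetune_epochs", "batch_size",
                     "cd_steps", "lne_frame_length", "n_training_windows"):
            if getattr(self, name) < (0 if name == "pretrain_epochs" else 1):
                problems.append(f"{name} out of range "
                                f"(got {getattr(self, name)})")
        if self.lambda1 < 0 or self.lambda2 < 0:
            problems.append("lambda1/lambda2 must be >= 0")
        if min(self.weights) < 0 or len(self.weights) != 3:
            problems.append(f"weights must be three non-negative values "
                            f"(got {self.weights})")
        if not 0 <= self.validation_fraction < 1:
            problems.append("validation_fraction must lie in [0, 1)")
        if self.rate <= 0:
            problems.append(f"rate must be > 0 (got {self.rate})")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        flat: dict = {}
        known = {f.name for f in fields(cls)}
        for key, value in raw.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        unknown = set(flat) - known
        if unknown:
            raise ValueError(
                f"unknown configuration fields: {sorted(unknown)}")
        for key in ("hidden_dims", "weights"):
            if key in flat:
                flat[key] = tuple(flat[key])
        if "lr_schedule" in flat:
            flat["lr_schedule"] = tuple(
                (int(e), float(r)) for e, r in flat["lr_schedule"])
        cfg = cls(**flat)
        cfg.validate()
        return cfg

    def override(self, **kwargs) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return self.from_mapping(data)

    def to_yaml(self) -> str:
        data = asdict(self)
        data["hidden_dims"] = list(self.hidden_dims)
        data["weights"] = list(self.weights)
        data["lr_schedule"] = [list(p) for p in self.lr_schedule]
        return yaml.safe_dump(data, sort_keys=True)
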