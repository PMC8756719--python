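"""Training configuration for the Deep Neural Map.

Defaults follow the reference protocol: Adam with batch size 64, 3500
autoencoder epochs, SOM learning rate 0.005 over 1500 epochs, and 1250
joint fine-tuning epochs. Tests and small studies override the epoch
counts downward.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

__all__ = ["TrainConfig", "DNMConfig"]


@dataclass(frozen=True)
class TrainConfig:
    """Iteration counts, step sizes and the joint-loss weight.

    ``joint_weight`` is the coefficient of the latent-to-BMU distance term
    added to the reconstruction loss during joint fine-tuning; the default
    keeps reconstruction dominant while tightening clusters around their
    nodes. During SOM pre-training the neighbourhood width decays from
    half the lattice span down to ``som_sigma_end``; the joint phase is a
    fine-tuning stage on an already-ordered map, so its width continues
    from ``joint_sigma_start`` down to ``joint_sigma_end`` instead of
    restarting lattice-wide.
    """

    ae_epochs: int = 3500
    som_epochs: int = 1500
    joint_epochs: int = 1250
    batch_size: int = 64
    ae_lr: float = 1e-3
    som_lr: float = 0.005
    joint_weight: float = 0.3
    som_sigma_end: float = 1.0
    joint_sigma_start: float = 1.0
    joint_sigma_end: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ae_epochs", "som_epochs", "joint_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.joint_weight < 0:
            raise ValueError("joint_weight must be >= 0")

    def replace(self, **kwargs) -> "TrainConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DNMConfig:
    """Everything needed to build and train a Deep Neural Map."""

    latent_dim: int = 25
    n_encoder_layers: int = 3
    activation: str = "tanh"
    l2_strength: float = 1e-5
    lattice_height: int = 15
    lattice_width: int = 15
    som_init: str = "data"  # "data": node weights sampled from latent codes; "uniform": U[0,1)
    train: TrainConfig = TrainConfig()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DNMConfig":
        d = dict(d)
        train = d.pop("train", {})
        return cls(train=TrainConfig(**train), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DNMConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
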