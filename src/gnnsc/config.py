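"""Run configuration: every stage's tunables in one serializable object.

A run is fully determined by (config, seed): per-stage seeds are derived
from the global seed with :class:`numpy.random.SeedSequence`, so rerunning
with the same resolved config reproduces every artifact byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig"]


@dataclass
class GNNConfig:
    layers: int = 10
    hidden_dim: int = 32
    activation: str = "relu"
    init: str = "diffusion"


@dataclass
class LinkConfig:
    gamma: int = 5
    lr: float = 0.01
    delta: float = 1e-4
    max_epochs: int = 200
    theta: float = 0.7
    scope: str = "two_hop"


@dataclass
class SpectralConfig:
    mu: int = 5
    omega: float | str = "auto"
    row_normalize: bool = True
    restarts: int = 10


@dataclass
class SelectConfig:
    scorer: str = "linear"
    params: dict = field(default_factory=dict)


@dataclass
class EvalConfig:
    k: int = 5
    classifier: str = "svm_linear"


@dataclass
class PipelineConfig:
    seed: int = 0
    zscore: bool = True
    keep_isolated: bool = True
    gnn: GNNConfig = field(default_factory=GNNConfig)
    link: LinkConfig = field(default_factory=LinkConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    select: SelectConfig = field(default_factory=SelectConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def stage_seeds(self) -> dict[str, int]:
        """Independent per-stage seeds derived from the global seed."""
        names = ["gnn_init", "link_samples", "spectral", "select", "cv"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)
        }

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        for key, sub in (
            ("gnn", GNNConfig),
            ("link", LinkConfig),
            ("spectral", SpectralConfig),
            ("select", SelectConfig),
            ("eval", EvalConfig),
        ):
            if key in data:
                kwargs[key] = sub(**data.pop(key))
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_mapping(json.loads(text))
        return cls.from_mapping(yaml.safe_load(text))
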