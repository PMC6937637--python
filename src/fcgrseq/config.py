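"""Pipeline configuration with the reference hyperparameter settings.

Defaults: pixelation level k=7 (128x128 FCGR images), f=30 retained DCT
frequencies per dimension, r=40 singular values, 20 kb chunks (at most 37
per genome), Euclidean lookup / cosine tree distances, average linkage,
top-20 candidate pools, and the 28-neighbor / count-2 consensus rule for
host prediction. Beyond these values accuracy improves little while cost
grows, so they are the package-wide defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    k: int = 7
    f: int = 30
    r: int = 40
    chunk_len: int = 20000
    max_chunks: int = 37
    tree_metric: str = "cosine"
    lookup_metric: str = "euclidean"
    linkage: str = "average"
    K_pool: int = 20
    n_neighbors: int = 28
    min_count: int = 2
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
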