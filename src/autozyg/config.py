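"""Run configuration: YAML-serialisable bundle of all stage configs.

Every command resolves its configuration (defaults, YAML file, flag
overrides), writes the resolved copy next to its outputs, and seeds every
random draw from the explicit seeds it contains, so a run can be
reproduced bit-for-bit from the resolved file alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .genotypes import QCConfig
from .maps import SubmapConfig
from .pipeline import DetectionConfig
from .simulate import ReplicateSpec, SyntheticGenomeConfig


@dataclass
class RunConfig:
    qc: QCConfig = field(default_factory=QCConfig)
    submaps: SubmapConfig = field(default_factory=SubmapConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    replicates: ReplicateSpec = field(default_factory=ReplicateSpec)
    genome: SyntheticGenomeConfig = field(default_factory=SyntheticGenomeConfig)
    fst: float = 0.15
    eps: float = 1e-3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = {}
        for f in fields(cls):
            if f.name not in data:
                continue
            val = data[f.name]
            if isinstance(val, dict) and f.name in _SUBTYPES:
                val = _SUBTYPES[f.name](**val)
            kwargs[f.name] = val
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


_SUBTYPES = {
    "qc": QCConfig,
    "submaps": SubmapConfig,
    "detection": DetectionConfig,
    "replicates": ReplicateSpec,
    "genome": SyntheticGenomeConfig,
}
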