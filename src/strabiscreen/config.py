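"""Run configuration: one serializable object tying a whole run together.

Every pipeline run resolves its configuration (paths, detector, model
recipes, threshold multipliers, input size, seed) and writes the resolved
copy beside its outputs, so any artifact can be regenerated from its
sidecar alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .regression import RegressorConfig

PACKAGE_VERSION = "0.1.0"


@dataclass
class RunConfig:
    detector: str = "synthetic"
    input_size_px: int = 128
    K: float = 1.5
    L: float = 1.5
    seed: int = 0
    output_dir: str = "out"
    paths: dict = field(default_factory=dict)
    direct: RegressorConfig = field(default_factory=RegressorConfig.direct_default)
    cross: RegressorConfig = field(default_factory=RegressorConfig.cross_default)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["direct"] = self.direct.to_dict()
        d["cross"] = self.cross.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("direct"), dict):
            d["direct"] = RegressorConfig.from_dict(d["direct"])
        if isinstance(d.get("cross"), dict):
            d["cross"] = RegressorConfig.from_dict(d["cross"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]

    def write_resolved(self, out_dir: str | Path) -> Path:
        """Write the resolved config (plus its hash and the package version)
        beside a run's outputs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = self.to_dict()
        payload["_provenance"] = {
            "config_hash": self.config_hash(),
            "package_version": PACKAGE_VERSION,
        }
        path = out / "run_config.yaml"
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path
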