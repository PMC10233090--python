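"""Single-source-of-truth pipeline configuration with YAML round-trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import ScanGeometry, TissueClass
from .postprocess import PostprocessConfig
from .segmentation import TrainingConfig, UNetConfig

__all__ = ["PipelineConfig"]

CLASS_CODE_TABLE = {cls.name: int(cls) for cls in TissueClass}


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, serialisable to YAML.

    Every stage reads its shared fields (geometry, seed, class codes) from
    here; serialisation round-trips byte-identically
    (write -> read -> write).
    """

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    unet: UNetConfig = field(default_factory=UNetConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    seed: int = 0
    class_codes: dict = field(default_factory=lambda: dict(CLASS_CODE_TABLE))

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "unet": {
                "depth": self.unet.depth,
                "base_channels": self.unet.base_channels,
                "input_patch": list(self.unet.input_patch),
                "n_classes": self.unet.n_classes,
            },
            "training": asdict(self.training),
            "postprocess": asdict(self.postprocess),
            "seed": self.seed,
            "class_codes": dict(self.class_codes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        u = d.get("unet", {})
        return cls(
            geometry=ScanGeometry.from_dict(d["geometry"]) if "geometry" in d else ScanGeometry(),
            unet=UNetConfig(
                depth=u.get("depth", 4),
                base_channels=u.get("base_channels", 16),
                input_patch=tuple(u.get("input_patch", (64, 64))),
                n_classes=u.get("n_classes", 7),
            ),
            training=TrainingConfig(**d.get("training", {})),
            postprocess=PostprocessConfig(**d.get("postprocess", {})),
            seed=d.get("seed", 0),
            class_codes=d.get("class_codes", dict(CLASS_CODE_TABLE)),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Short, stable digest used in provenance headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
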