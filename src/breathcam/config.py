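"""Pipeline configuration: every stage's parameters in one serialisable object.

Defaults follow the method's published operating point: spatial reduction
x8 from a 640x480 capture, 5 fps processing rate, >= 12 s windows,
labeling threshold T = 0.7, and the detector/estimator defaults of their
modules. YAML round-trips losslessly so a run can be reproduced from its
logged config alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .detector import DetectorConfig
from .estimator import DEFAULT_N_CLUSTERS
from .labeling import DEFAULT_THRESHOLD
from .metrics import DEFAULT_MIN_DISTANCE_S, DEFAULT_MIN_PROMINENCE_FRAC

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # preprocessing
    spatial_factor: int = 8
    target_fps: float = 5.0
    temporal_mode: str = "mean"
    window_seconds: float = 12.0
    hop_seconds: float = 1.0
    # labeling
    label_threshold: float = DEFAULT_THRESHOLD
    channel_mode: str = "mean"
    # training-set assembly
    train_hop_seconds: float = 3.0
    max_train_samples: int = 12000
    balance_ratio: float = 1.5  # at most this many negatives per positive
    # detector
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    # estimator
    n_clusters: int = DEFAULT_N_CLUSTERS
    # peaks
    min_distance_s: float = DEFAULT_MIN_DISTANCE_S
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC
    refine_peaks: bool = True
    # global
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "detector" in d and isinstance(d["detector"], dict):
            det = dict(d["detector"])
            for key in ("block_widths", "aug_scale_range", "aug_shift_range"):
                if key in det:
                    det[key] = tuple(det[key])
            d["detector"] = DetectorConfig(**det)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kw) -> "PipelineConfig":
        d = self.to_dict()
        d.update(kw)
        return PipelineConfig.from_dict(d)
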