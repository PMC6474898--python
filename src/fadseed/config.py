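"""Pipeline configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from fadseed.seed_imaging import SegmentationConfig


@dataclass
class PipelineConfig:
    """Settings for an end-to-end run (simulate -> segment -> analyze).

    quantile_cut is the tail fraction used for the unspotted/spotted
    classification (default 0.15 on each side); exact_test_threshold is the
    combined sample size up to which rank-sum p-values are enumerated
    exactly; alpha is only used for reporting.
    """

    output_dir: str = "results/pipeline"
    simulate: bool = True
    seeds_csv: Optional[str] = None
    image_dir: Optional[str] = None
    n_demo_images: int = 6
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    quantile_cut: float = 0.15
    exact_test_threshold: int = 12
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile_cut < 0.5:
            raise ValueError("quantile_cut must lie in (0, 0.5)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        seg = raw.pop("segmentation", None)
        cfg = cls(**raw)
        if seg is not None:
            cfg.segmentation = SegmentationConfig(**seg)
        return cfg

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))
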