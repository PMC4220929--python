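"""Run configuration: one versioned file of pipeline parameters.

The shipped defaults are the CD3/DAB profile: analysis on the 20x layer,
mask from the miniature (~1.25x) layer, three-class Otsu with the entropy
criterion, correction factor 1.3, threshold bounds [0.5, 1.0], nucleus
diameter gate 8-26 px, tissue gate 40 px at absolute threshold 0.03.
CLI flags override config values; config values override these defaults.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detection import DEFAULT_C_MAX, ThresholdSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    analysis_magnification: float = 20.0
    mask_magnification: float = 1.25
    nominal_magnification: float = 40.0  # assigned to untagged top pages
    tile_size: int = 2048
    min_keep: float = 0.01
    # masking
    blur_sigma: float = 2.0
    fuzz: float = 0.10
    min_region: int = 50
    # detection (CD3 profile)
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    min_diameter: float = 8.0
    max_diameter: float = 26.0
    c_max: float = DEFAULT_C_MAX
    tissue_smooth_sigma: float = 5.0
    tissue_threshold: float = 0.03
    tissue_min_diameter: float = 40.0
    restrict_to_tissue: bool = True
    # outputs
    save_tiles: bool = True
    save_overlays: bool = False
    workers: int = 1

    def to_yaml(self, path: str | os.PathLike) -> Path:
        data = dataclasses.asdict(self)
        path = Path(path)
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        thr = data.pop("threshold", None)
        cfg = cls(**data)
        if thr is not None:
            cfg.threshold = ThresholdSpec(**thr) if isinstance(thr, dict) else thr
        return cfg


def load_config(path: str | os.PathLike | None) -> RunConfig:
    """Load a YAML config; a missing path yields the default CD3 profile."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(data)
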