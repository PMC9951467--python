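"""Analysis configuration with YAML round-trip.

Defaults correspond to the standard pipeline: surface first-crossing at half
the A-line maximum with an 11x11 median filter, depth-histogram smoothing
over one axial resolution width, valley slab boundaries fixed at t=0, and
256-bin Otsu thresholds averaged over each subject's timepoint series.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class SurfaceConfig:
    frac: float = 0.5
    median_window: int = 11
    noise_floor: float | None = None
    reference_window: int = 41
    outlier_margin_um: float = 90.0
    # the series is acquired at one location; the t=0 profile serves the
    # whole series so that constriction cannot perturb the geometry reference
    fix_to_t0: bool = True


@dataclass
class LayersConfig:
    smooth_window_um: float = 30.0
    min_separation_um: float = 100.0
    boundary_rule: str = "valleys"
    fix_to_t0: bool = True


@dataclass
class QuantifyConfig:
    n_bins: int = 256
    centroid_weighting: str = "binary"


@dataclass
class StudyConfig:
    test_kind: str = "paired"      # "paired" (protocol default) or "welch"
    bonferroni: bool = False
    comparisons: list | None = None  # None -> default comparison list


@dataclass
class AnalysisConfig:
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)
    layers: LayersConfig = field(default_factory=LayersConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    study: StudyConfig = field(default_factory=StudyConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        cfg = cls()
        for section_name in ("surface", "layers", "quantify", "study"):
            section = data.get(section_name, {})
            target = getattr(cfg, section_name)
            for key, value in (section or {}).items():
                if not hasattr(target, key):
                    raise KeyError(f"unknown config key {section_name}.{key}")
                setattr(target, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))
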