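"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .densitometry import Thresholds


@dataclass
class SegmentationConfig:
    airway_hu_start: float = -960.0
    airway_hu_stop: float = -800.0
    airway_hu_step: float = 20.0
    airway_leak_factor: float = 2.0
    lung_upper_bound_hu: float = -200.0
    closing_radius: int = 2
    connectivity: int = 26
    fissure_sigma_mm: float = 2.0
    fissure_threshold: float = 10.0
    tps_smoothing: float = 1.0
    fallback_fraction: float = 0.55


@dataclass
class RegistrationConfig:
    beta_mm: float = 45.0
    lam: float = 8.0
    outlier_w: float = 0.1
    pitch_mm: float = 6.0
    max_iter: int = 300
    tol: float = 1e-7


@dataclass
class LacConfig:
    connectivity: int = 26
    min_core_depth: float = 2
    ratio_cut: float = 0.5
    min_voxels: int = 8


@dataclass
class ModelConfig:
    k_scales: int = 10
    alpha: float = 0.05
    folds: int = 5
    repeats: int = 30
    seed: int = 0
    stratify: bool = True
    reselect_per_fold: bool = True


@dataclass
class PipelineConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    lac: LacConfig = field(default_factory=LacConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    grid_cell_mm: float = 20.0
    output_dir: str = "bprm_out"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        sections = {
            "thresholds": Thresholds,
            "segmentation": SegmentationConfig,
            "registration": RegistrationConfig,
            "lac": LacConfig,
            "model": ModelConfig,
        }
        for key, klass in sections.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        valid = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in kwargs.items() if k in valid})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
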