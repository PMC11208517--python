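"""Analysis configuration: every densitometric and functional constant in one
place, overridable from YAML (or JSON — YAML is a superset)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Tuple

import yaml

#: default aeration boundaries (HU): normo [-860, -435], hypo (-435, -121),
#: non [-121, 121]; everything else is reported as "other".
DEFAULT_HU_BOUNDARIES = (-860.0, -435.0, -121.0, 121.0)

#: specific volume of parenchymal tissue, reciprocal of 1.065 g/ml.
DEFAULT_TISSUE_SPECIFIC_VOLUME = 1.0 / 1.065


@dataclass
class RegistrationParams:
    """Multi-resolution Demons settings.

    ``n_levels=3`` runs at 4x/2x/1x downsampling with
    ``iterations_per_level`` iterations from coarse to fine.
    """

    n_levels: int = 3
    iterations_per_level: Tuple[int, ...] = (100, 50, 25)
    update_smoothing_sigma_voxels: float = 1.5
    field_smoothing_sigma_voxels: float = 2.0
    laplacian_sigma_voxels: float = 1.0
    convergence_tol: float = 1e-4
    max_step_voxels: float = 1.25
    magnitude_cap_voxels: float = 20.0

    def __post_init__(self):
        self.iterations_per_level = tuple(int(i) for i in self.iterations_per_level)
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if len(self.iterations_per_level) != self.n_levels:
            raise ValueError("iterations_per_level must have n_levels entries")
        for name in ("update_smoothing_sigma_voxels", "field_smoothing_sigma_voxels",
                     "laplacian_sigma_voxels", "convergence_tol", "max_step_voxels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(i <= 0 for i in self.iterations_per_level):
            raise ValueError("iteration counts must be positive")


@dataclass
class SegmentationParams:
    threshold_hu: float = -200.0
    closing_radius_voxels: int = 2
    min_component_fraction: float = 0.10  # of the largest interior component
    #: recover dense consolidations that the air threshold misses (the study's
    #: learned segmenter includes them); per-component convex hull.
    fill_consolidation: bool = True


@dataclass
class AnalysisConfig:
    """Pipeline constants with the published defaults.

    ``hu_boundaries`` are the four strictly increasing aeration-compartment
    edges; ``calibration_percentiles`` are the (inspiratory SVg, expiratory
    SVg, delta-SVg) percentiles used for threshold calibration.
    """

    hu_boundaries: Tuple[float, float, float, float] = DEFAULT_HU_BOUNDARIES
    tissue_specific_volume: float = DEFAULT_TISSUE_SPECIFIC_VOLUME
    hu_clip: Tuple[float, float] = (-990.0, 1000.0)
    calibration_percentiles: Tuple[float, float, float] = (5.0, 5.0, 25.0)
    calibration_mode: str = "per_animal"  # or "pooled"
    calibration_groups: Optional[Tuple[str, ...]] = None  # None = all groups
    mixed_class: str = "low"  # route mixed Table-3 cases to "low" or "separate"
    sem_single: str = "zero"  # SEM for n=1: "zero" or "nan"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    output_dir: Optional[str] = None

    def __post_init__(self):
        b = tuple(float(x) for x in self.hu_boundaries)
        if len(b) != 4 or any(b[i] >= b[i + 1] for i in range(3)):
            raise ValueError("hu_boundaries must be 4 strictly increasing values")
        self.hu_boundaries = b
        if self.tissue_specific_volume <= 0:
            raise ValueError("tissue_specific_volume must be positive")
        p = tuple(float(x) for x in self.calibration_percentiles)
        if len(p) != 3 or any(not (0.0 < x < 100.0) for x in p):
            raise ValueError("calibration_percentiles must be 3 values in (0, 100)")
        self.calibration_percentiles = p
        if self.calibration_mode not in ("per_animal", "pooled"):
            raise ValueError("calibration_mode must be 'per_animal' or 'pooled'")
        if self.mixed_class not in ("low", "separate"):
            raise ValueError("mixed_class must be 'low' or 'separate'")
        if isinstance(self.segmentation, dict):
            self.segmentation = SegmentationParams(**self.segmentation)
        if isinstance(self.registration, dict):
            self.registration = RegistrationParams(**self.registration)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        for key in ("hu_boundaries", "hu_clip", "calibration_percentiles",
                    "calibration_groups"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
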