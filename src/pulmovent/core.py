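"""Core grid-aware containers shared by every pipeline stage.

Conventions
-----------
* Arrays are indexed ``(x, y, z)`` with the cranio-caudal axis last.
* Voxel indices are 0-based; world coordinates are
  ``origin_mm + index * spacing_mm``.
* HU values are stored as floating point regardless of source dtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import GridMismatchError

PHASES = ("P01", "P02")

#: labels used by :class:`LungLabelVolume`
BACKGROUND, LEFT_LUNG, RIGHT_LUNG = 0, 1, 2

REGIONS = ("whole", "left", "right")

GRID_SPACING_TOL_MM = 1e-6


def _as_vec3(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"{name} must have 3 components, got {arr.size}")
    return arr


@dataclass
class CTVolume:
    """A 3D scalar field of HU values on a regular grid.

    Parameters
    ----------
    values : ndarray
        3D array of HU values (stored as float).
    spacing_mm : array-like
        Per-axis voxel spacing in millimetres, strictly positive.
    origin_mm : array-like, optional
        World coordinate of voxel (0, 0, 0).
    phase : {"P01", "P02"}, optional
        Respiratory phase tag: end-inspiration (P01) or end-expiration (P02).
    """

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    phase: Optional[str] = None
    subject_id: Optional[str] = None
    day: Optional[int] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got {self.values.ndim}D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        self.spacing_mm = _as_vec3(self.spacing_mm, "spacing_mm")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be strictly positive")
        self.origin_mm = _as_vec3(self.origin_mm, "origin_mm")
        if self.phase is not None and self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_values(self, values: np.ndarray, phase: Optional[str] = None) -> "CTVolume":
        """Copy of this volume with new values (and optionally a new phase)."""
        out = replace(self, values=np.array(values, dtype=float))
        if phase is not None:
            out.phase = phase
        return out


@dataclass
class LungLabelVolume:
    """Voxel labels 0=background, 1=left lung, 2=right lung."""

    labels: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.all(lab == np.round(lab)):
                raise ValueError("labels must be integer valued")
            self.labels = lab.astype(np.int16)
        extra = set(np.unique(self.labels)) - {BACKGROUND, LEFT_LUNG, RIGHT_LUNG}
        if extra:
            raise ValueError(f"labels outside {{0,1,2}}: {sorted(extra)}")
        self.spacing_mm = _as_vec3(self.spacing_mm, "spacing_mm")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be strictly positive")
        self.origin_mm = _as_vec3(self.origin_mm, "origin_mm")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask for ``region`` in {'whole', 'left', 'right'}."""
        if region == "whole":
            return self.labels > 0
        if region == "left":
            return self.labels == LEFT_LUNG
        if region == "right":
            return self.labels == RIGHT_LUNG
        raise ValueError(f"unknown region {region!r}")


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement in mm on the fixed (P01) grid.

    The field maps fixed-grid coordinates to moving-image coordinates:
    ``warped_moving(x) = moving(x + u(x))`` (pull-back convention).
    """

    vectors: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    magnitude_cap_voxels: float = 20.0

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("vectors must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement vectors must be finite")
        self.spacing_mm = _as_vec3(self.spacing_mm, "spacing_mm")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be strictly positive")
        self.origin_mm = _as_vec3(self.origin_mm, "origin_mm")
        vox = self.vectors / self.spacing_mm
        mag = np.sqrt((vox ** 2).sum(axis=-1))
        if mag.max(initial=0.0) > self.magnitude_cap_voxels:
            raise ValueError(
                f"displacement magnitude {mag.max():.2f} voxels exceeds "
                f"sanity cap {self.magnitude_cap_voxels}"
            )

    @property
    def shape(self) -> tuple:
        return self.vectors.shape[:3]

    def as_voxels(self) -> np.ndarray:
        """Displacement in voxel units, shape (nx, ny, nz, 3)."""
        return self.vectors / self.spacing_mm


@dataclass
class GridCheck:
    """Structured result of a grid-compatibility test."""

    ok: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.ok


def _grid_of(obj):
    if isinstance(obj, CTVolume):
        return obj.values.shape, obj.spacing_mm
    if isinstance(obj, LungLabelVolume):
        return obj.labels.shape, obj.spacing_mm
    if isinstance(obj, DisplacementField):
        return obj.vectors.shape[:3], obj.spacing_mm
    raise TypeError(f"unsupported grid object {type(obj).__name__}")


def validate_grid_compatibility(a, b, spacing_tol_mm: float = GRID_SPACING_TOL_MM) -> GridCheck:
    """Check that two grid objects share shape and spacing.

    Passes iff shapes are equal and spacings agree within ``spacing_tol_mm``.
    """
    shape_a, spacing_a = _grid_of(a)
    shape_b, spacing_b = _grid_of(b)
    if shape_a != shape_b:
        return GridCheck(False, f"shape mismatch: {shape_a} vs {shape_b}")
    if np.any(np.abs(spacing_a - spacing_b) > spacing_tol_mm):
        return GridCheck(
            False,
            f"spacing mismatch: {tuple(spacing_a)} vs {tuple(spacing_b)} mm",
        )
    return GridCheck(True, "compatible")


def require_compatible(a, b, context: str = "") -> None:
    """Raise :class:`GridMismatchError` when grids are incompatible."""
    check = validate_grid_compatibility(a, b)
    if not check:
        prefix = f"{context}: " if context else ""
        raise GridMismatchError(prefix + check.reason)
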