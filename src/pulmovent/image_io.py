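"""NIfTI reading/writing for volumes, label maps and displacement fields."""

from __future__ import annotations

import logging
import os
from typing import Optional

import nibabel as nib
import numpy as np

from .core import CTVolume, DisplacementField, LungLabelVolume
from .errors import FormatError

log = logging.getLogger("pulmovent")


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    aff[:3, 3] = origin_mm
    return aff


def _load(path):
    if not os.path.exists(path):
        raise FormatError(f"file not found: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot parse {path} as NIfTI: {exc}") from exc
    return img


def _grid_from_header(img, path):
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if np.any(zooms <= 0):
        raise FormatError(f"{path}: non-positive voxel spacing {tuple(zooms)}")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return zooms, origin


def read_volume(path, phase: Optional[str] = None, subject_id: Optional[str] = None,
                day: Optional[int] = None) -> CTVolume:
    """Read a 3D scalar NIfTI volume of HU values.

    Refuses 4D input rather than guessing which hyper-slice was meant.
    """
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D scalar data, got {data.ndim}D")
    spacing, origin = _grid_from_header(img, path)
    return CTVolume(values=np.asarray(data, dtype=float), spacing_mm=spacing,
                    origin_mm=origin, phase=phase, subject_id=subject_id, day=day)


def write_volume(vol: CTVolume, path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32),
                          _affine(vol.spacing_mm, vol.origin_mm))
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, path)


def read_labels(path) -> LungLabelVolume:
    """Read an integer label NIfTI volume (0=background, 1=left, 2=right)."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D label data, got {data.ndim}D")
    spacing, origin = _grid_from_header(img, path)
    try:
        return LungLabelVolume(labels=np.rint(data).astype(np.int16),
                               spacing_mm=spacing, origin_mm=origin)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_labels(mask: LungLabelVolume, path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int16),
                          _affine(mask.spacing_mm, mask.origin_mm))
    img.header.set_zooms(tuple(mask.spacing_mm))
    nib.save(img, path)


def read_field(path) -> DisplacementField:
    """Read a 4D NIfTI displacement field (last axis = vector component, mm)."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(f"{path}: expected (nx, ny, nz, 3) field, got {data.shape}")
    spacing, origin = _grid_from_header(img, path)
    return DisplacementField(vectors=np.asarray(data, dtype=float),
                             spacing_mm=spacing, origin_mm=origin)


def write_field(field: DisplacementField, path) -> None:
    img = nib.Nifti1Image(field.vectors.astype(np.float32),
                          _affine(field.spacing_mm, field.origin_mm))
    nib.save(img, path)
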