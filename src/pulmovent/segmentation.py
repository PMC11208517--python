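"""Classical lung segmentation: air thresholding, border-component removal,
morphological cleanup, and a left/right split."""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import ball, convex_hull_image

from .config import SegmentationParams
from .core import (CTVolume, LungLabelVolume, require_compatible)
from .errors import FormatError, SegmentationError


def _border_component_ids(labeled: np.ndarray) -> set:
    ids = set()
    for axis in range(3):
        ids |= set(np.unique(np.take(labeled, 0, axis=axis)))
        ids |= set(np.unique(np.take(labeled, -1, axis=axis)))
    ids.discard(0)
    return ids


def segment_lungs(ct: CTVolume, params: Optional[SegmentationParams] = None) -> LungLabelVolume:
    """Segment left/right lungs from a thorax CT volume.

    Pipeline: threshold air (HU < ``threshold_hu``), drop border-connected
    air, keep the largest interior components, close and fill holes, and
    restrict to the body. Raises :class:`SegmentationError` on empty output.
    """
    params = params or SegmentationParams()
    air = ct.values < params.threshold_hu

    labeled, n = ndimage.label(air)
    if n == 0:
        raise SegmentationError("no air-range voxels below threshold")
    border = _border_component_ids(labeled)
    interior = np.asarray(
        [i for i in range(1, n + 1) if i not in border], dtype=np.int64)
    if interior.size == 0:
        raise SegmentationError("no interior air components (no body found?)")
    sizes = ndimage.sum_labels(np.ones_like(labeled, dtype=np.int64),
                               labeled, interior)
    keep = interior[sizes >= params.min_component_fraction * sizes.max()]
    lung = np.isin(labeled, keep)

    if params.closing_radius_voxels > 0:
        lung = ndimage.binary_closing(lung, ball(params.closing_radius_voxels))
    lung = ndimage.binary_fill_holes(lung)
    if params.fill_consolidation:
        lung = _fill_consolidation(lung)

    body = ndimage.binary_fill_holes(ct.values >= params.threshold_hu)
    lung &= body
    if not lung.any():
        raise SegmentationError("segmentation produced an empty lung mask")
    return split_left_right(lung, ct)


def _fill_consolidation(lung: np.ndarray) -> np.ndarray:
    """Per-component convex hull: dense (non-aerated) tissue at the lung
    surface is invisible to the air threshold but still belongs to the lung."""
    labeled, n = ndimage.label(lung)
    out = np.zeros_like(lung)
    for sl, idx in zip(ndimage.find_objects(labeled), range(1, n + 1)):
        comp = labeled[sl] == idx
        if comp.sum() < 4:  # qhull needs a non-degenerate simplex
            out[sl] |= comp
        else:
            out[sl] |= convex_hull_image(comp, offset_coordinates=False)
    return out


def split_left_right(lung_mask: np.ndarray, ct: Optional[CTVolume] = None) -> LungLabelVolume:
    """Assign left (1) / right (2) labels by centroid laterality.

    The two largest connected components are labelled by their centroid
    x coordinates; a fused single component is split at the sagittal plane
    through the body (or mask) centroid. Smaller x = left.
    """
    if not lung_mask.any():
        raise SegmentationError("empty lung mask")
    spacing = ct.spacing_mm if ct is not None else np.ones(3)
    origin = ct.origin_mm if ct is not None else np.zeros(3)
    labeled, n = ndimage.label(lung_mask)
    labels = np.zeros(lung_mask.shape, dtype=np.int16)
    if n >= 2:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled,
                                   np.arange(1, n + 1))
        order = np.argsort(sizes)[::-1][:2] + 1
        centroids = ndimage.center_of_mass(lung_mask, labeled, order)
        left_first = centroids[0][0] <= centroids[1][0]
        labels[labeled == order[0]] = 1 if left_first else 2
        labels[labeled == order[1]] = 2 if left_first else 1
    else:
        if ct is not None:
            body = ndimage.binary_fill_holes(ct.values > -500)
            cx = ndimage.center_of_mass(body)[0] if body.any() else \
                ndimage.center_of_mass(lung_mask)[0]
        else:
            cx = ndimage.center_of_mass(lung_mask)[0]
        xs = np.arange(lung_mask.shape[0])[:, None, None]
        labels[lung_mask & (xs <= cx)] = 1
        labels[lung_mask & (xs > cx)] = 2
    return LungLabelVolume(labels=labels, spacing_mm=spacing, origin_mm=origin)


def load_external_mask(path, ct: CTVolume,
                       label_mapping: Optional[Dict[int, int]] = None) -> LungLabelVolume:
    """Load a user-supplied mask, validate its grid and relabel to {0,1,2}."""
    import nibabel as nib

    img = nib.load(path)
    data = np.rint(np.asanyarray(img.dataobj))
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D label data, got {data.ndim}D")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    present = set(int(v) for v in np.unique(data))
    if label_mapping is not None:
        out = np.zeros(data.shape, dtype=np.int16)
        for src, dst in label_mapping.items():
            if dst not in (0, 1, 2):
                raise FormatError(f"mapping target {dst} outside {{0,1,2}}")
            out[data == src] = dst
        data = out
    elif not present <= {0, 1, 2}:
        raise FormatError(
            f"{path}: labels {sorted(present - {0, 1, 2})} outside {{0,1,2}} "
            "and no label_mapping provided")
    mask = LungLabelVolume(labels=data.astype(np.int16), spacing_mm=spacing,
                           origin_mm=origin)
    require_compatible(mask, ct, "external mask")
    return mask
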