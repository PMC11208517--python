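"""Deformable registration: Laplacian-of-Gaussian prefiltering, a
multi-resolution Demons solver, warping and Jacobian utilities.

The Demons force is the classic normalised optical-flow update

    u = (m - f) * grad(f) / (|grad(f)|^2 + (m - f)^2)

accumulated coarse-to-fine with Gaussian smoothing of both the per-iteration
update (fluid-like) and the accumulated field (diffusion-like). The field is
defined on the fixed (P01) grid and maps fixed coordinates to moving (P02)
coordinates (pull-back convention).
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .config import RegistrationParams
from .core import (CTVolume, DisplacementField, LungLabelVolume,
                   require_compatible)
from .errors import RegistrationError


def laplacian_prefilter(ct: CTVolume, sigma_voxels: float = 1.0) -> CTVolume:
    """Laplacian-of-Gaussian response, used only to drive registration.

    Kills global intensity offsets (which vary with lung inflation) while
    keeping edge structure. Never feed the output into densitometry.
    """
    if sigma_voxels <= 0:
        raise ValueError("sigma must be positive")
    # mean-subtract first: the truncated discrete LoG kernel does not sum
    # exactly to zero, so a raw constant would leak through
    values = ct.values - ct.values.mean()
    filtered = ndimage.gaussian_laplace(values, sigma=sigma_voxels)
    return ct.with_values(filtered)


def _downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    sm = ndimage.gaussian_filter(arr, sigma=0.5 * factor)
    return ndimage.zoom(sm, 1.0 / factor, order=1)


def _warp_array(arr: np.ndarray, disp_vox: np.ndarray, order: int,
                cval: float) -> np.ndarray:
    idx = np.indices(arr.shape, dtype=float)
    coords = idx + np.moveaxis(disp_vox, -1, 0)
    return ndimage.map_coordinates(arr, coords, order=order, mode="constant",
                                   cval=cval)


def _demons_level(fixed: np.ndarray, moving: np.ndarray, disp: np.ndarray,
                  iterations: int, params: RegistrationParams) -> np.ndarray:
    grad = np.stack(np.gradient(fixed), axis=-1)
    grad_sq = (grad ** 2).sum(axis=-1)
    # suppress the force where there is no structure to match: the classic
    # denominator lets noise in flat regions inject O(1) random steps
    gate = grad_sq > 1e-3 * grad_sq.max()
    eps = 1e-12
    prev_mse = None
    prev_step = None
    min_step = np.inf
    growing = 0
    for _ in range(iterations):
        warped = _warp_array(moving, disp, order=1, cval=0.0)
        diff = fixed - warped
        denom = grad_sq + diff ** 2
        update = diff[..., None] * grad / np.maximum(denom, eps)[..., None]
        update[~gate] = 0.0
        mag = np.sqrt((update ** 2).sum(axis=-1))
        scale = np.minimum(1.0, params.max_step_voxels / np.maximum(mag, eps))
        update *= scale[..., None]
        for c in range(3):
            update[..., c] = ndimage.gaussian_filter(
                update[..., c], params.update_smoothing_sigma_voxels)
        disp = disp + update
        for c in range(3):
            disp[..., c] = ndimage.gaussian_filter(
                disp[..., c], params.field_smoothing_sigma_voxels)

        # a slow creep toward the force/smoothing equilibrium is normal;
        # true divergence shows sustained growth well above the best step
        mean_step = float(mag.mean())
        min_step = min(min_step, mean_step)
        if prev_step is not None and mean_step > prev_step * 1.001:
            growing += 1
            if growing >= 10 and mean_step > 1.5 * min_step:
                raise RegistrationError(
                    "demons diverged: update magnitude grew for 10 iterations")
        else:
            growing = 0
        prev_step = mean_step

        mse = float((diff ** 2).mean())
        if prev_mse is not None and abs(prev_mse - mse) <= \
                params.convergence_tol * max(prev_mse, eps):
            break
        prev_mse = mse
    return disp


def demons_multiresolution(
    fixed_filtered: CTVolume,
    moving_filtered: CTVolume,
    params: Optional[RegistrationParams] = None,
) -> DisplacementField:
    """Coarse-to-fine Demons registration of two (pre-filtered) volumes.

    Returns the full-resolution displacement field in mm on the fixed grid.
    """
    params = params or RegistrationParams()
    require_compatible(fixed_filtered, moving_filtered, "registration")
    fixed = fixed_filtered.values
    moving = moving_filtered.values
    # normalise jointly so force magnitudes are scale-free
    scale = max(np.abs(fixed).max(), np.abs(moving).max(), 1e-12)
    fixed = fixed / scale
    moving = moving / scale

    factors = [2 ** (params.n_levels - 1 - i) for i in range(params.n_levels)]
    disp = None
    for level, factor in enumerate(factors):
        f = _downsample(fixed, factor)
        m = _downsample(moving, factor)
        if disp is None:
            disp = np.zeros(f.shape + (3,))
        else:
            zoom = [t / s for t, s in zip(f.shape, disp.shape[:3])]
            disp = np.stack(
                [ndimage.zoom(disp[..., c], zoom, order=1) * zoom[c]
                 for c in range(3)], axis=-1)
        disp = _demons_level(f, m, disp, params.iterations_per_level[level],
                             params)
    vectors = disp * fixed_filtered.spacing_mm
    return DisplacementField(vectors=vectors,
                             spacing_mm=fixed_filtered.spacing_mm,
                             origin_mm=fixed_filtered.origin_mm,
                             magnitude_cap_voxels=params.magnitude_cap_voxels)


def warp_volume(
    moving: Union[CTVolume, LungLabelVolume], field: DisplacementField,
) -> Union[CTVolume, LungLabelVolume]:
    """Resample ``moving`` onto the fixed grid through ``field``.

    HU volumes are interpolated trilinearly with out-of-field samples at
    -1000 HU; label volumes use nearest neighbour with background fill.
    """
    require_compatible(moving, field, "warp")
    disp_vox = field.as_voxels()
    if isinstance(moving, CTVolume):
        warped = _warp_array(moving.values, disp_vox, order=1, cval=-1000.0)
        return CTVolume(values=warped, spacing_mm=moving.spacing_mm,
                        origin_mm=moving.origin_mm, phase=moving.phase,
                        subject_id=moving.subject_id, day=moving.day)
    warped = _warp_array(moving.labels.astype(np.int16), disp_vox, order=0,
                         cval=0)
    return LungLabelVolume(labels=warped.astype(np.int16),
                           spacing_mm=moving.spacing_mm,
                           origin_mm=moving.origin_mm)


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """det(I + grad u) by central differences, per voxel."""
    u = field.vectors
    spacing = field.spacing_mm
    g = np.empty(u.shape[:3] + (3, 3))
    for i in range(3):
        for j in range(3):
            g[..., i, j] = np.gradient(u[..., i], spacing[j], axis=j)
        g[..., i, i] += 1.0
    return np.linalg.det(g)


def invert_field(field: DisplacementField, n_iter: int = 30) -> DisplacementField:
    """Numeric inverse by fixed-point iteration: v(y) = -u(y + v(y))."""
    u_vox = field.as_voxels()
    v = np.zeros_like(u_vox)
    idx = np.indices(u_vox.shape[:3], dtype=float)
    for _ in range(n_iter):
        coords = idx + np.moveaxis(v, -1, 0)
        sampled = np.stack(
            [ndimage.map_coordinates(u_vox[..., c], coords, order=1,
                                     mode="nearest") for c in range(3)],
            axis=-1)
        v = -sampled
    return DisplacementField(vectors=v * field.spacing_mm,
                             spacing_mm=field.spacing_mm,
                             origin_mm=field.origin_mm,
                             magnitude_cap_voxels=field.magnitude_cap_voxels)


def register_pair(
    fixed: CTVolume, moving: CTVolume,
    params: Optional[RegistrationParams] = None,
) -> DisplacementField:
    """LoG-prefilter both volumes and run multi-resolution Demons."""
    params = params or RegistrationParams()
    f = laplacian_prefilter(fixed, params.laplacian_sigma_voxels)
    m = laplacian_prefilter(moving, params.laplacian_sigma_voxels)
    return demons_multiresolution(f, m, params)
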