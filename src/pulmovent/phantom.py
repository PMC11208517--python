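"""Synthetic thorax phantoms: paired inspiratory/expiratory micro-CT volumes
with exact ground truth (masks, displacement, Jacobian, lesion labels).

The deformation is an analytic caudo-cranial compression applied along the
z axis only, so its Jacobian determinant is exactly ``1 + du_z/dz`` and the
field is invertible by 1D fixed-point iteration. The expiratory image obeys
the mass-conserving intensity rule

    HU_exp = (HU_insp + 1000) / J - 1000

which couples density change to local volume change: a pure-gas voxel
(-1000 HU) stays -1000 HU under any compression, while parenchyma densifies.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import DEFAULT_HU_BOUNDARIES
from .core import CTVolume, DisplacementField, LungLabelVolume, REGIONS
from .errors import DeformationError, InfeasibleSpecError, InvalidSpecError
from . import image_io

AERATION_CLASSES = ("normo", "hypo", "non", "other")


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of a synthetic thorax."""

    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: float = 0.05
    body_hu: float = 40.0
    parenchyma_hu_mean: float = -550.0
    parenchyma_hu_sd: float = 45.0
    noise_sd_hu: float = 25.0
    #: correlation length of parenchyma/lesion texture; reconstruction
    #: kernels correlate CT speckle, and voxel-iid texture would decorrelate
    #: under sub-voxel warping. 0 = white texture.
    texture_sigma_voxels: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise InvalidSpecError("grid_shape must be 3 positive integers")
        if self.voxel_spacing_mm <= 0:
            raise InvalidSpecError("voxel_spacing_mm must be positive")
        for name in ("body_hu", "parenchyma_hu_mean"):
            v = getattr(self, name)
            if not -1000.0 <= v <= 1000.0:
                raise InvalidSpecError(f"{name}={v} outside [-1000, 1000] HU")
        if self.parenchyma_hu_sd < 0 or self.noise_sd_hu < 0:
            raise InvalidSpecError("HU standard deviations must be non-negative")
        if self.texture_sigma_voxels < 0:
            raise InvalidSpecError("texture_sigma_voxels must be non-negative")

    @property
    def spacing(self) -> np.ndarray:
        return np.full(3, float(self.voxel_spacing_mm))


@dataclass
class LesionSpec:
    """Focal fibrotic blobs of near-tissue density planted inside the lung."""

    count: int = 3
    radius_mm_range: Tuple[float, float] = (0.15, 0.35)
    hu_mean: float = 20.0
    hu_sd: float = 40.0
    placement_bias: str = "apical_left"  # or "apical", "uniform"

    def __post_init__(self):
        if self.count < 0:
            raise InvalidSpecError("lesion count must be >= 0")
        lo, hi = self.radius_mm_range
        if lo <= 0 or hi < lo:
            raise InvalidSpecError("radius_mm_range must be positive and ordered")
        if self.hu_mean <= -121.0:
            raise InvalidSpecError(
                "lesion hu_mean must exceed -121 HU (non-aerated range)")
        if self.placement_bias not in ("apical_left", "apical", "uniform"):
            raise InvalidSpecError(f"unknown placement_bias {self.placement_bias!r}")


@dataclass
class DeformationModel:
    """Analytic respiratory compression along the cranio-caudal (z) axis."""

    amplitude_mm: float = 0.12
    smoothness_mm: float = 0.3
    lesion_stiffness: float = 0.9

    def __post_init__(self):
        if self.amplitude_mm < 0:
            raise InvalidSpecError("amplitude_mm must be >= 0")
        if self.smoothness_mm <= 0:
            raise InvalidSpecError("smoothness_mm must be positive")
        if not 0.0 <= self.lesion_stiffness <= 1.0:
            raise InvalidSpecError("lesion_stiffness must be in [0, 1]")


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a synthetic scan pair."""

    mask: LungLabelVolume
    mask_p02: LungLabelVolume
    displacement: DisplacementField
    lesion_labels: np.ndarray
    true_jacobian: np.ndarray
    true_compartment_fractions: Dict[str, Dict[str, float]]


DEFAULT_GROUPS = ("SAL", "BLM", "NINT_7_28", "NINT_14_28")


@dataclass
class CohortPlan:
    """Longitudinal cohort layout: groups, timepoints and lesion growth."""

    n_per_group: int = 3
    groups: Tuple[str, ...] = DEFAULT_GROUPS
    timepoints_days: Tuple[int, ...] = (0, 7, 14, 21, 28)
    treatment_start_day: Dict[str, int] = field(
        default_factory=lambda: {"NINT_7_28": 7, "NINT_14_28": 14})
    peak_lesion_count: int = 6
    treatment_attenuation: float = 0.25
    lesion_spec: LesionSpec = field(default_factory=LesionSpec)
    deformation: DeformationModel = field(default_factory=DeformationModel)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise InvalidSpecError("n_per_group must be >= 1")
        self.timepoints_days = tuple(sorted(int(d) for d in self.timepoints_days))
        if 0 not in self.timepoints_days:
            raise InvalidSpecError("timepoints must include day 0 (basal set)")
        if not 0.0 <= self.treatment_attenuation <= 1.0:
            raise InvalidSpecError("treatment_attenuation must be in [0, 1]")
        for group, day in self.treatment_start_day.items():
            if group in self.groups and day not in self.timepoints_days:
                raise InvalidSpecError(
                    f"treatment_start_day {day} for {group} not in timepoints")

    def lesion_count(self, group: str, day: int) -> int:
        """Per-group lesion-count trajectory; 0 at day 0 for every group."""
        if group == "SAL" or day <= 0:
            return 0
        effective = float(day)
        start = self.treatment_start_day.get(group)
        if start is not None and day > start:
            effective = start + self.treatment_attenuation * (day - start)
        max_day = max(self.timepoints_days)
        return int(round(self.peak_lesion_count * effective / max_day))


# ---------------------------------------------------------------------------
# anatomy


def _texture_field(rng: np.random.Generator, shape,
                   sigma_voxels: float) -> np.ndarray:
    """Unit-variance texture with the given correlation length."""
    tex = rng.standard_normal(shape)
    if sigma_voxels > 0:
        tex = ndimage.gaussian_filter(tex, sigma_voxels)
        tex /= max(tex.std(), 1e-12)
    return tex


def _anatomy_masks(shape) -> Tuple[np.ndarray, np.ndarray]:
    """Body ellipsoid and left/right lung label map for a given grid."""
    nx, ny, nz = shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2

    def ellipsoid(c, semi):
        return (((x - c[0]) / semi[0]) ** 2 + ((y - c[1]) / semi[1]) ** 2
                + ((z - c[2]) / semi[2]) ** 2) <= 1.0

    body = ellipsoid((cx, cy, cz), (0.42 * nx, 0.42 * ny, 0.46 * nz))
    lung_semi = (0.14 * nx, 0.24 * ny, 0.30 * nz)
    left = ellipsoid((cx - 0.19 * nx, cy, cz), lung_semi)
    right = ellipsoid((cx + 0.19 * nx, cy, cz), lung_semi)
    labels = np.zeros(shape, dtype=np.int16)
    labels[left] = 1
    labels[right] = 2
    return body, labels


def generate_anatomy(spec: PhantomSpec) -> Tuple[CTVolume, LungLabelVolume]:
    """Build the end-inspiratory thorax: two ellipsoidal lungs in a body.

    Outside-body voxels sit at -1000 HU; lung voxels are drawn from the
    parenchyma distribution; Gaussian reconstruction noise (``noise_sd_hu``)
    is added everywhere.
    """
    if any(n < 32 for n in spec.grid_shape):
        raise InvalidSpecError(
            f"grid {spec.grid_shape} too small to contain two lungs "
            "(needs >= 32 voxels per axis)")
    rng = np.random.default_rng(spec.rng_seed)
    body, labels = _anatomy_masks(spec.grid_shape)
    values = np.full(spec.grid_shape, -1000.0)
    values[body] = spec.body_hu
    lung = labels > 0
    tex = _texture_field(rng, spec.grid_shape, spec.texture_sigma_voxels)
    values[lung] = spec.parenchyma_hu_mean + spec.parenchyma_hu_sd * tex[lung]
    if spec.noise_sd_hu > 0:
        values += rng.normal(0.0, spec.noise_sd_hu, size=spec.grid_shape)
    np.clip(values, -1000.0, 1000.0, out=values)
    ct = CTVolume(values=values, spacing_mm=spec.spacing, phase="P01")
    mask = LungLabelVolume(labels=labels, spacing_mm=spec.spacing)
    return ct, mask


def plant_lesions(ct: CTVolume, mask: LungLabelVolume, lesions: LesionSpec,
                  seed: int, texture_sigma_voxels: float = 1.0,
                  ) -> Tuple[CTVolume, np.ndarray]:
    """Overwrite spherical lung patches with lesion-intensity draws.

    With a fixed seed, the first ``k`` lesions of any two specs differing
    only in ``count`` coincide, so lesion burden is nested across counts.
    """
    lesion_labels = np.zeros(ct.shape, dtype=bool)
    if lesions.count == 0:
        return ct.with_values(ct.values), lesion_labels
    lung = mask.labels > 0
    lung_idx = np.argwhere(lung)
    spacing = ct.spacing_mm
    extent_mm = (lung_idx.max(axis=0) - lung_idx.min(axis=0) + 1) * spacing
    if lesions.radius_mm_range[1] * 2 >= extent_mm.min():
        raise InvalidSpecError("lesion diameter exceeds lung extent")
    mean_r = np.mean(lesions.radius_mm_range)
    requested = lesions.count * 4 / 3 * np.pi * mean_r ** 3
    lung_volume = lung.sum() * ct.voxel_volume_mm3
    if requested > 0.8 * lung_volume:
        raise InfeasibleSpecError(
            f"requested lesion volume {requested:.3g} mm^3 exceeds 80% of "
            f"lung volume {lung_volume:.3g} mm^3")

    # placement weights: apex = cranial (low z); left lung favoured 3:1
    z = lung_idx[:, 2].astype(float)
    z01 = (z - z.min()) / max(z.max() - z.min(), 1.0)
    weights = np.ones(len(lung_idx))
    if lesions.placement_bias in ("apical", "apical_left"):
        weights *= np.exp(-3.0 * z01)
    if lesions.placement_bias == "apical_left":
        weights *= np.where(mask.labels[tuple(lung_idx.T)] == 1, 3.0, 1.0)
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    # draw the texture first so that, for a fixed seed, the first k lesions
    # of specs differing only in count coincide (nested lesion burden)
    tex = _texture_field(rng, ct.shape, texture_sigma_voxels)
    values = np.array(ct.values)
    grids = np.ogrid[: ct.shape[0], : ct.shape[1], : ct.shape[2]]
    for _ in range(lesions.count):
        center = lung_idx[rng.choice(len(lung_idx), p=weights)]
        r_mm = rng.uniform(*lesions.radius_mm_range)
        ball = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing))
        ball = (ball <= r_mm ** 2) & lung
        lesion_labels |= ball
        values[ball] = lesions.hu_mean + lesions.hu_sd * tex[ball]
    return ct.with_values(values), lesion_labels


# ---------------------------------------------------------------------------
# deformation


def mass_conserving_hu(hu, jacobian):
    """HU after a local volume change by factor ``jacobian``.

    Density scales inversely with volume: HU' = (HU + 1000)/J - 1000.
    Pure gas (-1000 HU) is a fixed point — gas carries no mass.
    """
    return (np.asarray(hu, dtype=float) + 1000.0) / jacobian - 1000.0


def _analytic_uz_mm(shape, spacing, mask_labels, model: DeformationModel,
                    lesion_labels: Optional[np.ndarray]) -> np.ndarray:
    """z-displacement (mm) of the inspiration->expiration map on the P01 grid."""
    nx, ny, nz = shape
    lung = mask_labels > 0
    zs = np.where(lung.any(axis=(0, 1)))[0]
    z0, z1 = int(zs.min()), int(zs.max())
    z = np.arange(nz, dtype=float)
    t = np.clip((z - z0) / max(z1 - z0, 1), 0.0, 1.0)
    ramp = 3 * t ** 2 - 2 * t ** 3  # smoothstep, 0 cranial -> 1 caudal
    sigma_vox = model.smoothness_mm / spacing[2]
    ramp = ndimage.gaussian_filter1d(ramp, sigma_vox, mode="nearest")

    x = np.arange(nx, dtype=float)[:, None]
    y = np.arange(ny, dtype=float)[None, :]
    sx, sy = 0.45 * nx, 0.45 * ny
    w_xy = np.exp(-(((x - (nx - 1) / 2) / sx) ** 2
                    + ((y - (ny - 1) / 2) / sy) ** 2) / 2.0)

    uz = -model.amplitude_mm * w_xy[:, :, None] * ramp[None, None, :]
    if lesion_labels is not None and lesion_labels.any() and model.lesion_stiffness > 0:
        # saturate the window so the whole lesion (not just its core) is
        # rigid; the transition to mobile parenchyma sits outside the lesion
        soft = np.clip(2.5 * ndimage.gaussian_filter(lesion_labels.astype(float), 1.0),
                       0.0, 1.0)
        uz = uz * (1.0 - model.lesion_stiffness * soft)
    return uz


def _invert_uz(uz_vox: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Fixed-point inverse of the z-only map z -> z + uz(x, y, z).

    Returns, for every expiratory grid voxel, the inspiratory z coordinate
    (in voxels) of the material point occupying it.
    """
    nx, ny, nz = uz_vox.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    zinv = kk.astype(float)
    coords = np.empty((3,) + uz_vox.shape)
    coords[0], coords[1] = ii, jj
    for _ in range(n_iter):
        coords[2] = zinv
        u_at = ndimage.map_coordinates(uz_vox, coords, order=1, mode="nearest")
        zinv = kk - u_at
    return zinv


def apply_respiratory_deformation(
    ct_insp: CTVolume,
    mask: LungLabelVolume,
    model: DeformationModel,
    lesion_labels: Optional[np.ndarray] = None,
) -> Tuple[CTVolume, DisplacementField, np.ndarray]:
    """Derive the expiratory phase from the inspiratory one.

    Returns ``(ct_exp, displacement, true_jacobian)`` where the displacement
    (mm, on the P01 grid) follows the pull-back registration convention and
    the Jacobian is the local volume-change ratio of the compression.
    """
    spacing = ct_insp.spacing_mm
    if model.amplitude_mm == 0.0:
        zero = np.zeros(ct_insp.shape + (3,))
        fieldv = DisplacementField(vectors=zero, spacing_mm=spacing,
                                   origin_mm=ct_insp.origin_mm)
        return (ct_insp.with_values(ct_insp.values, phase="P02"), fieldv,
                np.ones(ct_insp.shape))

    uz_mm = _analytic_uz_mm(ct_insp.shape, spacing, mask.labels, model,
                            lesion_labels)
    jac = 1.0 + np.gradient(uz_mm, spacing[2], axis=2)
    if jac.min() <= 0:
        raise DeformationError(
            f"deformation not invertible: min Jacobian {jac.min():.3f} <= 0")

    uz_vox = uz_mm / spacing[2]
    zinv = _invert_uz(uz_vox)
    nx, ny, nz = ct_insp.shape
    ii, jj, _ = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                            indexing="ij")
    coords = np.stack([ii.astype(float), jj.astype(float), zinv])
    hu_src = ndimage.map_coordinates(ct_insp.values, coords, order=1,
                                     mode="constant", cval=-1000.0)
    jac_src = ndimage.map_coordinates(jac, coords, order=1, mode="nearest")
    hu_exp = mass_conserving_hu(hu_src, jac_src)
    np.clip(hu_exp, -1000.0, 1000.0, out=hu_exp)

    vectors = np.zeros(ct_insp.shape + (3,))
    vectors[..., 2] = uz_mm
    fieldv = DisplacementField(vectors=vectors, spacing_mm=spacing,
                               origin_mm=ct_insp.origin_mm)
    ct_exp = CTVolume(values=hu_exp, spacing_mm=spacing,
                      origin_mm=ct_insp.origin_mm, phase="P02",
                      subject_id=ct_insp.subject_id, day=ct_insp.day)
    return ct_exp, fieldv, jac


def _warp_labels_to_exp(mask: LungLabelVolume, uz_vox_field: np.ndarray) -> LungLabelVolume:
    zinv = _invert_uz(uz_vox_field)
    nx, ny, nz = mask.shape
    ii, jj, _ = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                            indexing="ij")
    coords = np.stack([ii.astype(float), jj.astype(float), zinv])
    warped = ndimage.map_coordinates(mask.labels, coords, order=0,
                                     mode="constant", cval=0)
    return LungLabelVolume(labels=warped.astype(np.int16),
                           spacing_mm=mask.spacing_mm, origin_mm=mask.origin_mm)


# ---------------------------------------------------------------------------
# paired phantom + truth


def compartment_fractions(values: np.ndarray, mask: LungLabelVolume,
                          boundaries=DEFAULT_HU_BOUNDARIES) -> Dict[str, Dict[str, float]]:
    """Exact per-region voxel-count fractions per aeration class."""
    b0, b1, b2, b3 = boundaries
    out: Dict[str, Dict[str, float]] = {}
    for region in REGIONS:
        hu = values[mask.region_mask(region)]
        n = hu.size
        if n == 0:
            out[region] = {c: 0.0 for c in AERATION_CLASSES}
            continue
        normo = int(np.count_nonzero((hu >= b0) & (hu <= b1)))
        hypo = int(np.count_nonzero((hu > b1) & (hu < b2)))
        non = int(np.count_nonzero((hu >= b2) & (hu <= b3)))
        out[region] = {
            "normo": normo / n,
            "hypo": hypo / n,
            "non": non / n,
            "other": (n - normo - hypo - non) / n,
        }
    return out


def make_phantom_pair(
    spec: PhantomSpec,
    lesions: Optional[LesionSpec] = None,
    model: Optional[DeformationModel] = None,
) -> Tuple[CTVolume, CTVolume, PhantomTruth]:
    """Generate an (inspiratory, expiratory, truth) triple.

    Anatomy and lesions are built noise-free, deformed mass-conservingly,
    and independent reconstruction noise is added to each phase last.
    """
    model = model if model is not None else DeformationModel()
    clean = replace(spec, noise_sd_hu=0.0)
    ct, mask = generate_anatomy(clean)
    lesion_labels = np.zeros(ct.shape, dtype=bool)
    if lesions is not None and lesions.count > 0:
        ct, lesion_labels = plant_lesions(ct, mask, lesions,
                                          seed=spec.rng_seed + 101,
                                          texture_sigma_voxels=spec.texture_sigma_voxels)
    ct_exp, fieldv, jac = apply_respiratory_deformation(ct, mask, model,
                                                        lesion_labels)
    mask_p02 = (_warp_labels_to_exp(mask, fieldv.as_voxels()[..., 2])
                if model.amplitude_mm > 0 else
                LungLabelVolume(labels=np.array(mask.labels),
                                spacing_mm=mask.spacing_mm,
                                origin_mm=mask.origin_mm))
    rng = np.random.default_rng(spec.rng_seed + 202)
    p01 = ct.values + (rng.normal(0, spec.noise_sd_hu, ct.shape)
                       if spec.noise_sd_hu > 0 else 0.0)
    p02 = ct_exp.values + (rng.normal(0, spec.noise_sd_hu, ct.shape)
                           if spec.noise_sd_hu > 0 else 0.0)
    p01 = np.clip(p01, -1000.0, 1000.0)
    p02 = np.clip(p02, -1000.0, 1000.0)
    ct_p01 = CTVolume(values=p01, spacing_mm=spec.spacing, phase="P01")
    ct_p02 = CTVolume(values=p02, spacing_mm=spec.spacing, phase="P02")
    truth = PhantomTruth(
        mask=mask,
        mask_p02=mask_p02,
        displacement=fieldv,
        lesion_labels=lesion_labels,
        true_jacobian=jac,
        true_compartment_fractions=compartment_fractions(p01, mask),
    )
    return ct_p01, ct_p02, truth


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(plan: CohortPlan, spec: PhantomSpec, out_dir) -> pd.DataFrame:
    """Write one (P01, P02) pair plus truth files per subject per timepoint.

    Returns the manifest (also written to ``out_dir/manifest.csv``) with
    columns subject_id, group, day, p01_path, p02_path, mask_path,
    truth_prefix; paths are relative to ``out_dir``.
    """
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory not writable: {out_dir}")
    rows = []
    for gi, group in enumerate(plan.groups):
        for si in range(plan.n_per_group):
            subject_id = f"{group}_{si + 1:02d}"
            ss = np.random.SeedSequence([plan.rng_seed, gi, si])
            anat_seed, lesion_seed, noise_seed = ss.generate_state(3).tolist()
            for day in plan.timepoints_days:
                sub_spec = replace(spec, rng_seed=int(anat_seed), noise_sd_hu=0.0)
                ct, mask = generate_anatomy(sub_spec)
                count = plan.lesion_count(group, day)
                lesion_labels = np.zeros(ct.shape, dtype=bool)
                if count > 0:
                    day_lesions = replace(plan.lesion_spec, count=count)
                    ct, lesion_labels = plant_lesions(
                        ct, mask, day_lesions, seed=int(lesion_seed),
                        texture_sigma_voxels=spec.texture_sigma_voxels)
                ct_exp, fieldv, jac = apply_respiratory_deformation(
                    ct, mask, plan.deformation, lesion_labels)
                rng = np.random.default_rng([int(noise_seed), day])
                sd = spec.noise_sd_hu
                p01 = np.clip(ct.values + rng.normal(0, sd, ct.shape)
                              if sd > 0 else ct.values, -1000, 1000)
                p02 = np.clip(ct_exp.values + rng.normal(0, sd, ct.shape)
                              if sd > 0 else ct_exp.values, -1000, 1000)

                subdir = os.path.join(out_dir, subject_id)
                os.makedirs(subdir, exist_ok=True)
                rel = lambda name: os.path.join(subject_id, name)  # noqa: E731
                names = {
                    "p01": rel(f"day{day:02d}_P01.nii.gz"),
                    "p02": rel(f"day{day:02d}_P02.nii.gz"),
                    "mask": rel(f"day{day:02d}_mask.nii.gz"),
                }
                truth_prefix = rel(f"day{day:02d}_truth")
                image_io.write_volume(
                    CTVolume(p01, spec.spacing, phase="P01",
                             subject_id=subject_id, day=day),
                    os.path.join(out_dir, names["p01"]))
                image_io.write_volume(
                    CTVolume(p02, spec.spacing, phase="P02",
                             subject_id=subject_id, day=day),
                    os.path.join(out_dir, names["p02"]))
                image_io.write_labels(mask, os.path.join(out_dir, names["mask"]))
                image_io.write_labels(
                    LungLabelVolume(lesion_labels.astype(np.int16),
                                    spec.spacing),
                    os.path.join(out_dir, truth_prefix + "_lesions.nii.gz"))
                image_io.write_field(
                    fieldv, os.path.join(out_dir, truth_prefix + "_disp.nii.gz"))
                fractions = compartment_fractions(p01, mask)
                with open(os.path.join(out_dir, truth_prefix + ".json"), "w") as fh:
                    json.dump({"lesion_fraction":
                               float(lesion_labels.sum() / (mask.labels > 0).sum()),
                               "compartment_fractions": fractions}, fh, indent=1)
                rows.append({"subject_id": subject_id, "group": group, "day": day,
                             "p01_path": names["p01"], "p02_path": names["p02"],
                             "mask_path": names["mask"],
                             "truth_prefix": truth_prefix})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
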