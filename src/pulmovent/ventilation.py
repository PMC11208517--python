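"""Specific gas volume (SVg) maps, delta-SVg ventilation maps, percentile
threshold calibration, and the Normal/Low/Fibrosis voxel classifier.

SVg = 1000/(HU + 1000) - SV_tissue (ml/g), with SV_tissue = 1/1.065 by
default; delta-SVg = SVg_P01 - SVg_warped_P02. Classification:

    Normal:   delta >= beta
    Fibrosis: delta < beta and SVg_P01 < alpha_I and SVg_P02 < alpha_E
    Low:      everything else (including the mixed single-condition cases)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import DEFAULT_TISSUE_SPECIFIC_VOLUME
from .core import CTVolume, LungLabelVolume, REGIONS, require_compatible
from .errors import CalibrationError, GridMismatchError

#: integer codes of the per-voxel class map (0 = outside)
CLASS_NORMAL, CLASS_LOW, CLASS_FIBROSIS, CLASS_MIXED = 1, 2, 3, 4


@dataclass
class SVgMap:
    """Per-voxel specific gas volume (ml/g), NaN outside the lung mask."""

    values: np.ndarray
    mask: np.ndarray
    phase_tag: str  # "P01" or "warped_P02"

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise GridMismatchError("SVg values and mask shapes differ")

    def lung_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class DeltaSVgMap:
    """Per-voxel inspiratory-minus-expiratory SVg (ml/g)."""

    values: np.ndarray
    mask: np.ndarray

    def lung_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class VentilationThresholds:
    """Calibrated (alpha_I, alpha_E, beta) triple in ml/g."""

    alpha_I: float
    alpha_E: float
    beta: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("alpha_I", "alpha_E", "beta"):
            if not np.isfinite(getattr(self, name)):
                raise CalibrationError(f"{name} is not finite")

    def as_dict(self) -> dict:
        return {"alpha_I": float(self.alpha_I), "alpha_E": float(self.alpha_E),
                "beta": float(self.beta), "provenance": dict(self.provenance)}


@dataclass
class VentilationReport:
    """Three-class voxel map plus per-region percentages."""

    class_map: np.ndarray
    percentages: Dict[str, Dict[str, float]]  # region -> {normal, low, fibrosis[, mixed]}


def specific_gas_volume(
    ct: CTVolume, mask: np.ndarray,
    tissue_sv: float = DEFAULT_TISSUE_SPECIFIC_VOLUME,
    hu_clip: Tuple[float, float] = (-990.0, 1000.0),
    phase_tag: Optional[str] = None,
) -> SVgMap:
    """SVg = 1000/(HU_clipped + 1000) - tissue_sv inside ``mask``.

    HU is clipped to ``hu_clip`` before the division because the formula
    diverges at -1000 HU.
    """
    if tissue_sv <= 0:
        raise ValueError("tissue_sv must be positive")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ct.shape:
        raise GridMismatchError("mask shape differs from volume")
    hu = np.clip(ct.values, *hu_clip)
    values = np.full(ct.shape, np.nan)
    values[mask] = 1000.0 / (hu[mask] + 1000.0) - tissue_sv
    return SVgMap(values=values, mask=mask,
                  phase_tag=phase_tag or ct.phase or "P01")


def delta_svg(svg_p01: SVgMap, svg_warped_p02: SVgMap) -> DeltaSVgMap:
    """Voxel-wise SVg_P01 - SVg_P02 on the intersection of both masks."""
    if svg_p01.values.shape != svg_warped_p02.values.shape:
        raise GridMismatchError("SVg maps are on different grids")
    both = svg_p01.mask & svg_warped_p02.mask
    values = np.full(svg_p01.values.shape, np.nan)
    values[both] = svg_p01.values[both] - svg_warped_p02.values[both]
    return DeltaSVgMap(values=values, mask=both)


def calibrate_thresholds(
    basal_pairs: Sequence[Tuple[np.ndarray, np.ndarray, np.ndarray]],
    percentiles: Tuple[float, float, float] = (5.0, 5.0, 25.0),
    mode: str = "per_animal",
    cohort_id: str = "",
) -> VentilationThresholds:
    """Calibrate (alpha_I, alpha_E, beta) from day-0 scan pairs.

    Each entry of ``basal_pairs`` holds the lung-voxel value arrays
    (svg_p01, svg_warped_p02, delta_svg) of one baseline animal.

    ``per_animal`` (default): take each animal's own percentiles and average
    them across the cohort. ``pooled``: concatenate all animals' voxels and
    take a single percentile.
    """
    if len(basal_pairs) == 0:
        raise CalibrationError("empty calibration cohort")
    p_i, p_e, p_d = percentiles
    cleaned = []
    for k, (s1, s2, dd) in enumerate(basal_pairs):
        s1, s2, dd = (np.asarray(a)[np.isfinite(np.asarray(a))]
                      for a in (s1, s2, dd))
        if dd.size == 0:
            raise CalibrationError(f"calibration pair {k} lacks a delta-SVg map")
        if s1.size == 0 or s2.size == 0:
            raise CalibrationError(f"calibration pair {k} lacks SVg values")
        cleaned.append((s1, s2, dd))
    if mode == "per_animal":
        alpha_i = float(np.mean([np.percentile(s1, p_i) for s1, _, _ in cleaned]))
        alpha_e = float(np.mean([np.percentile(s2, p_e) for _, s2, _ in cleaned]))
        beta = float(np.mean([np.percentile(dd, p_d) for _, _, dd in cleaned]))
    elif mode == "pooled":
        alpha_i = float(np.percentile(np.concatenate([s1 for s1, _, _ in cleaned]), p_i))
        alpha_e = float(np.percentile(np.concatenate([s2 for _, s2, _ in cleaned]), p_e))
        beta = float(np.percentile(np.concatenate([dd for _, _, dd in cleaned]), p_d))
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")
    thresholds = VentilationThresholds(
        alpha_I=alpha_i, alpha_E=alpha_e, beta=beta,
        provenance={"cohort_id": cohort_id, "n_animals": len(cleaned),
                    "percentiles": [p_i, p_e, p_d], "mode": mode})
    if thresholds.beta <= 0:
        import warnings

        warnings.warn("calibrated beta <= 0: basal cohort may not be "
                      "compressive", stacklevel=2)
    return thresholds


def classify_values(
    svg1: np.ndarray, svg2: np.ndarray, delta: np.ndarray,
    thresholds: VentilationThresholds, mixed_class: str = "low",
) -> np.ndarray:
    """Vectorised three-way classification of flat voxel arrays.

    Returns int codes (CLASS_NORMAL/LOW/FIBROSIS, plus CLASS_MIXED when
    ``mixed_class='separate'``).
    """
    normal = delta >= thresholds.beta
    low_i = svg1 < thresholds.alpha_I
    low_e = svg2 < thresholds.alpha_E
    fibrosis = ~normal & low_i & low_e
    codes = np.where(normal, CLASS_NORMAL,
                     np.where(fibrosis, CLASS_FIBROSIS, CLASS_LOW))
    if mixed_class == "separate":
        mixed = ~normal & ~fibrosis & (low_i ^ low_e)
        codes = np.where(mixed, CLASS_MIXED, codes)
    return codes.astype(np.int16)


def classify_voxels(
    svg_p01: SVgMap, svg_warped_p02: SVgMap, delta: DeltaSVgMap,
    thresholds: VentilationThresholds,
    label_volume: Optional[LungLabelVolume] = None,
    mixed_class: str = "low",
) -> VentilationReport:
    """Assign every analysable lung voxel exactly one ventilation class.

    The denominator is the intersection of the P01 and warped-P02 masks;
    per-region percentages are computed against the region's analysable
    voxels and sum to 100 exactly (by counting).
    """
    if thresholds is None:
        raise CalibrationError("thresholds not calibrated")
    valid = delta.mask
    class_map = np.zeros(valid.shape, dtype=np.int16)
    class_map[valid] = classify_values(
        svg_p01.values[valid], svg_warped_p02.values[valid],
        delta.values[valid], thresholds, mixed_class)

    regions = REGIONS if label_volume is not None else ("whole",)
    percentages: Dict[str, Dict[str, float]] = {}
    for region in regions:
        rmask = (label_volume.region_mask(region) & valid
                 if label_volume is not None else valid)
        codes = class_map[rmask]
        n = codes.size
        pct = {}
        names = [("normal", CLASS_NORMAL), ("low", CLASS_LOW),
                 ("fibrosis", CLASS_FIBROSIS)]
        if mixed_class == "separate":
            names.append(("mixed", CLASS_MIXED))
        for name, code in names:
            pct[name] = 100.0 * np.count_nonzero(codes == code) / n if n else 0.0
        percentages[region] = pct
    return VentilationReport(class_map=class_map, percentages=percentages)


def svg_arrays_for_pair(
    ct_p01: CTVolume, warped_p02: CTVolume,
    mask_p01: np.ndarray, warped_mask_p02: np.ndarray,
    tissue_sv: float = DEFAULT_TISSUE_SPECIFIC_VOLUME,
    hu_clip: Tuple[float, float] = (-990.0, 1000.0),
) -> Tuple[SVgMap, SVgMap, DeltaSVgMap]:
    """Convenience: both SVg maps plus their delta for one registered pair."""
    svg1 = specific_gas_volume(ct_p01, mask_p01, tissue_sv, hu_clip, "P01")
    svg2 = specific_gas_volume(warped_p02, warped_mask_p02, tissue_sv, hu_clip,
                               "warped_P02")
    return svg1, svg2, delta_svg(svg1, svg2)
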