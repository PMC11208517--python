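"""Morphological biomarkers: lung volume, mean attenuation, aeration
compartments, gas/tissue decomposition and tidal volume."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .config import DEFAULT_HU_BOUNDARIES
from .core import CTVolume, LungLabelVolume, require_compatible
from .errors import PulmoventError


class EmptyRegionError(PulmoventError):
    pass


@dataclass
class AerationReport:
    """All densitometric biomarkers for one region of one phase."""

    region: str
    phase: Optional[str]
    volume_mm3: float
    mla_hu: float
    pct_normo: float
    pct_hypo: float
    pct_non: float
    pct_other: float
    gas_volume_mm3: float
    tissue_volume_mm3: float
    pct_gas: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _region_values(ct: CTVolume, mask: LungLabelVolume, region: str) -> np.ndarray:
    require_compatible(ct, mask, "aeration")
    values = ct.values[mask.region_mask(region)]
    if values.size == 0:
        raise EmptyRegionError(f"region {region!r} is empty")
    return values


def mean_lung_attenuation(ct: CTVolume, mask: LungLabelVolume, region: str = "whole") -> float:
    """Arithmetic mean HU over the region's voxels (MLA)."""
    return float(_region_values(ct, mask, region).mean())


def lung_volume(mask: LungLabelVolume, region: str = "whole") -> float:
    """Region volume in mm^3 (voxel count x voxel volume)."""
    return float(np.count_nonzero(mask.region_mask(region)) * mask.voxel_volume_mm3)


def aeration_compartments(
    ct: CTVolume, mask: LungLabelVolume, region: str = "whole",
    boundaries: Tuple[float, float, float, float] = DEFAULT_HU_BOUNDARIES,
) -> Tuple[float, float, float, float]:
    """Percentages (normo, hypo, non, other) of region voxels by HU range.

    Normo = [b0, b1] closed, hypo = (b1, b2) open, non = [b2, b3] closed;
    everything else (hyper-aerated below b0 or dense above b3) is "other".
    The denominator is all region voxels.
    """
    b = tuple(float(x) for x in boundaries)
    if len(b) != 4 or any(b[i] >= b[i + 1] for i in range(3)):
        raise ValueError("boundaries must be 4 strictly increasing values")
    hu = _region_values(ct, mask, region)
    n = hu.size
    normo = np.count_nonzero((hu >= b[0]) & (hu <= b[1]))
    hypo = np.count_nonzero((hu > b[1]) & (hu < b[2]))
    non = np.count_nonzero((hu >= b[2]) & (hu <= b[3]))
    other = n - normo - hypo - non
    return (100.0 * normo / n, 100.0 * hypo / n,
            100.0 * non / n, 100.0 * other / n)


def gas_tissue_decomposition(
    ct: CTVolume, mask: LungLabelVolume, region: str = "whole",
) -> Tuple[float, float, float]:
    """Split region volume into gas and tissue via g = clamp(-HU/1000, 0, 1).

    Returns (gas_volume_mm3, tissue_volume_mm3, pct_gas).
    """
    hu = _region_values(ct, mask, region)
    g = np.clip(-hu / 1000.0, 0.0, 1.0)
    vv = mask.voxel_volume_mm3
    gas = float(g.sum() * vv)
    tissue = float((1.0 - g).sum() * vv)
    return gas, tissue, 100.0 * gas / (hu.size * vv)


def tidal_volume(mask_p01: LungLabelVolume, mask_p02: LungLabelVolume,
                 region: str = "whole") -> float:
    """Inspiratory minus expiratory segmented volume (mm^3).

    Negative values are reported, not clamped — they flag segmentation or
    registration faults.
    """
    return lung_volume(mask_p01, region) - lung_volume(mask_p02, region)


def aeration_report(
    ct: CTVolume, mask: LungLabelVolume, region: str = "whole",
    boundaries: Tuple[float, float, float, float] = DEFAULT_HU_BOUNDARIES,
) -> AerationReport:
    """Assemble every densitometric biomarker for one region."""
    normo, hypo, non, other = aeration_compartments(ct, mask, region, boundaries)
    gas, tissue, pct_gas = gas_tissue_decomposition(ct, mask, region)
    return AerationReport(
        region=region,
        phase=ct.phase,
        volume_mm3=lung_volume(mask, region),
        mla_hu=mean_lung_attenuation(ct, mask, region),
        pct_normo=normo, pct_hypo=hypo, pct_non=non, pct_other=other,
        gas_volume_mm3=gas, tissue_volume_mm3=tissue, pct_gas=pct_gas,
    )
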