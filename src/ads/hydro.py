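"""Peri-ventricular strips and hydrocephalus ratio features from an ADC map.

Two strips are built around the merged lateral-ventricle sub-regions: OLV,
the band just outside the ventricles, and ILV, the band just inside. On the
ADC map, voxels above the CSF threshold (default 0.0018 mm^2/s) are CSF,
voxels below it are tissue; voxels exactly at the threshold are neither.

gamma_OLVR = non-CSF fraction of OLV (low values: ventricles larger than the
template expects, i.e. enlargement). gamma_ILVR = CSF fraction of ILV (low
values: ventricles compressed or shifted off the template).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import BinaryLesionMask, LabeledVolume, ScalarVolume, grids_compatible

__all__ = [
    "StripPair",
    "HydroFeatures",
    "DEFAULT_CSF_THRESHOLD",
    "DEFAULT_STRIP_WIDTH",
    "build_ventricle_strips",
    "hydro_features",
    "hydro_flags",
]

DEFAULT_CSF_THRESHOLD = 0.0018  # mm^2/s
DEFAULT_STRIP_WIDTH = 5  # voxel layers


@dataclass
class StripPair:
    """Outside (OLV) and inside (ILV) ventricular strips."""

    olv: BinaryLesionMask
    ilv: BinaryLesionMask
    width_voxels: int


@dataclass(frozen=True)
class HydroFeatures:
    gamma_olvr: float
    gamma_ilvr: float
    csf_threshold: float

    def __post_init__(self) -> None:
        for name in ("gamma_olvr", "gamma_ilvr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")


def _box(width: int) -> np.ndarray:
    # Chebyshev ball of radius `width`: one dilation step adds one voxel layer
    # in every direction, so `width` layers == a (2*width+1)^3 box.
    return np.ones((2 * width + 1,) * 3, dtype=bool)


def build_ventricle_strips(
    ventricles: LabeledVolume, width: int = DEFAULT_STRIP_WIDTH
) -> StripPair:
    """Build the OLV/ILV strips by box dilation/erosion of the merged
    ventricle labels by ``width`` voxel layers, clipped to the grid."""
    if width < 1:
        raise ValueError("strip width must be >= 1 voxel")
    union = ventricles.labels > 0
    if not union.any():
        raise ValueError("ventricle atlas has no labeled voxels")
    selem = _box(width)
    dilated = ndimage.binary_dilation(union, structure=selem)
    eroded = ndimage.binary_erosion(union, structure=selem)
    olv = dilated & ~union
    ilv = union & ~eroded
    return StripPair(
        olv=BinaryLesionMask(grid=ventricles.grid, values=olv.astype(np.uint8)),
        ilv=BinaryLesionMask(grid=ventricles.grid, values=ilv.astype(np.uint8)),
        width_voxels=width,
    )


def hydro_features(
    adc: ScalarVolume,
    strips: StripPair,
    csf_threshold: float = DEFAULT_CSF_THRESHOLD,
) -> HydroFeatures:
    """Compute gamma_OLVR and gamma_ILVR from an ADC map and a strip pair.

    Both inequalities are strict: a voxel exactly at the threshold counts as
    neither CSF nor non-CSF.
    """
    if csf_threshold <= 0:
        raise ValueError("csf_threshold must be positive")
    if not (
        grids_compatible(adc.grid, strips.olv.grid)
        and grids_compatible(adc.grid, strips.ilv.grid)
    ):
        raise ValueError("ADC map and strips on incompatible grids")
    # Unit guard: ADC in mm^2/s is O(1e-3); values near 1 suggest a scaled map
    # (e.g. 1e-6 mm^2/s integer convention) that must be rescaled explicitly.
    if float(np.percentile(adc.values, 99)) > 1.0:
        raise ValueError(
            "ADC intensities look scaled (99th percentile > 1.0); rescale the map "
            "to mm^2/s (e.g. via --adc-scale) before computing hydro features"
        )
    olv = strips.olv.as_bool()
    ilv = strips.ilv.as_bool()
    if not olv.any() or not ilv.any():
        raise ValueError("empty ventricular strip")
    vals = adc.values
    gamma_olvr = float((vals[olv] < csf_threshold).sum()) / int(olv.sum())
    gamma_ilvr = float((vals[ilv] > csf_threshold).sum()) / int(ilv.sum())
    return HydroFeatures(
        gamma_olvr=gamma_olvr, gamma_ilvr=gamma_ilvr, csf_threshold=csf_threshold
    )


def hydro_flags(
    features: HydroFeatures, cohort_means: tuple[float, float]
) -> tuple[bool, bool]:
    """Ventricular-enlargement and compression flags against cohort means.

    enlargement: gamma_OLVR strictly below the cohort mean gamma_OLVR;
    compression (or midline shift): gamma_ILVR strictly below the cohort
    mean gamma_ILVR.
    """
    mean_olvr, mean_ilvr = cohort_means
    for m in (mean_olvr, mean_ilvr):
        if not 0.0 <= m <= 1.0:
            raise ValueError("cohort means must lie in [0, 1]")
    return features.gamma_olvr < mean_olvr, features.gamma_ilvr < mean_ilvr
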