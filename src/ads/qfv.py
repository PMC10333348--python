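"""Quantitative feature vectors: per-ROI injury fractions plus log-ml volume.

Each QFV component is the proportion of an atlas ROI occupied by the infarct
mask; the natural log of the lesion volume in ml is carried alongside. A
Dice-based quality-control index flags gross mismatch between a subject's
brain contour and the atlas brain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import BinaryLesionMask, LabeledVolume, grids_compatible

__all__ = ["QFVector", "QCIndex", "extract_qfv", "lesion_volume", "qc_index"]


@dataclass
class QFVector:
    """Ordered per-ROI injury fractions for one atlas scheme.

    Fractions are kept at full precision; use :meth:`rounded` for the
    2-decimal display convention.
    """

    scheme: str
    fractions: dict[str, float]
    lesion_volume_ml: float
    lesion_volume_log_ml: float
    roi_voxels: dict[str, int] = field(default_factory=dict)
    lesion_voxels: dict[str, int] = field(default_factory=dict)
    unassigned_voxels: int = 0

    def __post_init__(self) -> None:
        for roi, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {roi!r} outside [0, 1]: {f}")
        if self.lesion_volume_ml <= 0:
            raise ValueError("lesion volume must be positive")
        if not math.isclose(
            self.lesion_volume_log_ml, math.log(self.lesion_volume_ml), abs_tol=1e-9
        ):
            raise ValueError("lesion_volume_log_ml is not ln(lesion_volume_ml)")

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Display fractions with round-half-up at ``ndigits`` decimals."""
        scale = 10**ndigits
        return {
            roi: math.floor(f * scale + 0.5) / scale for roi, f in self.fractions.items()
        }

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "fractions": dict(self.fractions),
            "lesion_volume_ml": self.lesion_volume_ml,
            "lesion_volume_log_ml": self.lesion_volume_log_ml,
            "roi_voxels": dict(self.roi_voxels),
            "lesion_voxels": dict(self.lesion_voxels),
            "unassigned_voxels": self.unassigned_voxels,
        }


@dataclass(frozen=True)
class QCIndex:
    """Dice overlap between subject and atlas brain contours."""

    dice: float
    flagged: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.dice <= 1.0:
            raise ValueError("dice outside [0, 1]")


def lesion_volume(mask: BinaryLesionMask) -> tuple[float, float]:
    """Lesion volume in ml and its natural log.

    ml = lesion voxel count x voxel volume (mm^3) / 1000. Raises on an empty
    mask: reporting requires a detected infarct, and log(0) is undefined.
    """
    n = mask.n_voxels
    if n == 0:
        raise ValueError("empty lesion mask: no infarct to quantify")
    ml = n * mask.grid.voxel_volume_mm3 / 1000.0
    return ml, math.log(ml)


def extract_qfv(mask: BinaryLesionMask, atlas: LabeledVolume) -> QFVector:
    """Per-ROI injury fractions of ``mask`` against ``atlas``.

    For each ROI r: fraction_r = |{v : mask(v)=1 and label(v)=r}| / |ROI r|.
    Lesion voxels falling outside every labeled ROI count toward the volume
    but toward no fraction; their number is reported as ``unassigned_voxels``.
    """
    if not grids_compatible(mask.grid, atlas.grid):
        raise ValueError("mask and atlas grids are incompatible")
    ml, log_ml = lesion_volume(mask)  # raises on empty mask

    lesioned = mask.as_bool()
    labels = atlas.labels
    max_id = max(atlas.roi_ids, default=0)
    roi_counts = np.bincount(labels.ravel(), minlength=max_id + 1)
    hit_counts = np.bincount(labels[lesioned].ravel(), minlength=max_id + 1)

    fractions: dict[str, float] = {}
    roi_voxels: dict[str, int] = {}
    lesion_voxels: dict[str, int] = {}
    for row in atlas.table:
        n_roi = int(roi_counts[row.id])
        if n_roi == 0:
            raise ValueError(f"ROI {row.name!r} (id {row.id}) has zero voxels")
        n_hit = int(hit_counts[row.id])
        fractions[row.name] = n_hit / n_roi
        roi_voxels[row.name] = n_roi
        lesion_voxels[row.name] = n_hit

    unassigned = int(lesioned.sum() - hit_counts[1:].sum())
    return QFVector(
        scheme=atlas.table[0].scheme if atlas.table else "unknown",
        fractions=fractions,
        lesion_volume_ml=ml,
        lesion_volume_log_ml=log_ml,
        roi_voxels=roi_voxels,
        lesion_voxels=lesion_voxels,
        unassigned_voxels=unassigned,
    )


def qc_index(
    subject_brain: BinaryLesionMask,
    atlas_brain: BinaryLesionMask,
    threshold: float = 0.90,
) -> QCIndex:
    """Dice agreement between subject and atlas brain masks.

    dice = 2|A ^ B| / (|A| + |B|); flagged when below ``threshold``.
    """
    if not grids_compatible(subject_brain.grid, atlas_brain.grid):
        raise ValueError("brain masks on incompatible grids")
    a = subject_brain.as_bool()
    b = atlas_brain.as_bool()
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise ValueError("both brain masks are empty")
    dice = 2.0 * int((a & b).sum()) / denom
    return QCIndex(dice=dice, flagged=dice < threshold)
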