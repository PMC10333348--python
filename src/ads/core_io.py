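"""Shared spatial data types, NIfTI I/O and output bundling.

All volumes in one case live on a single common grid (a template space such
as MNI); nothing here resamples. Voxel indices are 0-based, world space is
RAS and world ``x > 0`` is the right hemisphere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "LabeledVolume",
    "ScalarVolume",
    "BinaryLesionMask",
    "LabelRow",
    "SCHEMES",
    "grids_compatible",
    "read_labeled_volume",
    "read_scalar_volume",
    "read_lesion_mask",
    "write_volume",
    "write_label_table",
    "write_report_bundle",
]

SCHEMES = ("arterial", "structural", "aspects", "ventricle", "brainmask")

#: absolute tolerance (mm) for affine agreement between companion volumes
GRID_ATOL = 1e-4


@dataclass(frozen=True)
class VolumeGrid:
    """Sampling grid: array shape plus 4x4 voxel-to-world (mm) affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_dims(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_x(self) -> np.ndarray:
        """World x coordinate of every voxel (broadcast to ``shape``)."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        a = self.affine
        return a[0, 0] * ii + a[0, 1] * jj + a[0, 2] * kk + a[0, 3]


def grids_compatible(a: VolumeGrid, b: VolumeGrid, atol: float = GRID_ATOL) -> bool:
    """True iff shapes match and affines agree within ``atol`` mm."""
    return a.shape == b.shape and bool(
        np.allclose(a.affine, b.affine, atol=atol, rtol=0.0)
    )


@dataclass(frozen=True)
class LabelRow:
    id: int
    name: str
    scheme: str

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        if self.id <= 0:
            raise ValueError("label ids must be positive (0 is background)")


@dataclass
class LabeledVolume:
    """Integer parcellation on a grid with a label table (id, name, scheme)."""

    grid: VolumeGrid
    labels: np.ndarray
    table: list[LabelRow]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label array must be integer")
        if self.labels.shape != self.grid.shape:
            raise ValueError("label array shape does not match grid")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels).tolist()) - {0}
        known = {row.id for row in self.table}
        missing = present - known
        if missing:
            raise ValueError(
                f"labels {sorted(missing)} present in array but absent from table"
            )

    @property
    def roi_ids(self) -> list[int]:
        return [row.id for row in self.table]

    @property
    def roi_names(self) -> list[str]:
        return [row.name for row in self.table]

    def name_of(self, roi_id: int) -> str:
        for row in self.table:
            if row.id == roi_id:
                return row.name
        raise KeyError(roi_id)

    def roi_mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id

    def voxel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


@dataclass
class ScalarVolume:
    """Real-valued map on a grid; for ADC the units are mm^2/s."""

    grid: VolumeGrid
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("value array shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar volume contains non-finite values")


@dataclass
class BinaryLesionMask:
    """{0,1} volume on the atlas grid; the infarct core (or any binary mask)."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.values = arr.astype(np.uint8)
        if self.values.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)


# ---------------------------------------------------------------------------
# NIfTI + table I/O
# ---------------------------------------------------------------------------


def _load_nifti(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, VolumeGrid(shape=data.shape, affine=np.asarray(img.affine))


def read_label_table(table_path: str | Path) -> list[LabelRow]:
    """Read a TSV label table with columns id, name, scheme."""
    table_path = Path(table_path)
    if not table_path.exists():
        raise FileNotFoundError(table_path)
    df = pd.read_csv(table_path, sep="\t", dtype={"id": int, "name": str, "scheme": str})
    required = {"id", "name", "scheme"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    return [LabelRow(int(r.id), str(r.name), str(r.scheme)) for r in df.itertuples()]


def read_labeled_volume(path: str | Path, table_path: str | Path) -> LabeledVolume:
    """Load a parcellation NIfTI together with its TSV label table."""
    data, grid = _load_nifti(path)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError(f"{path}: parcellation voxels are not integral")
        data = rounded.astype(np.int32)
    return LabeledVolume(grid=grid, labels=data, table=read_label_table(table_path))


def read_scalar_volume(path: str | Path, units: str = "") -> ScalarVolume:
    data, grid = _load_nifti(path)
    return ScalarVolume(grid=grid, values=data.astype(float), units=units)


def read_lesion_mask(path: str | Path) -> BinaryLesionMask:
    data, grid = _load_nifti(path)
    return BinaryLesionMask(grid=grid, values=(np.rint(data) > 0).astype(np.uint8))


def write_volume(
    volume: LabeledVolume | ScalarVolume | BinaryLesionMask, path: str | Path
) -> Path:
    path = Path(path)
    if isinstance(volume, LabeledVolume):
        data = volume.labels.astype(np.int32)
    elif isinstance(volume, BinaryLesionMask):
        data = volume.values.astype(np.uint8)
    else:
        data = volume.values.astype(np.float32)
    nib.save(nib.Nifti1Image(data, volume.grid.affine), str(path))
    return path


def write_label_table(table: Sequence[LabelRow], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"id": [r.id for r in table], "name": [r.name for r in table],
         "scheme": [r.scheme for r in table]}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Output bundling
# ---------------------------------------------------------------------------


def write_report_bundle(report, qfv, preds, outdir: str | Path) -> dict[str, Path]:
    """Write the four case outputs: report text, JSON record, QFV CSV,
    prediction CSV (label, probability and Shapley contributions per ROI).

    ``qfv`` may be a single QFVector or a sequence of them (one per scheme);
    ``preds`` a RegionPredictionSet or sequence thereof.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    qfvs = list(qfv) if isinstance(qfv, (list, tuple)) else [qfv]
    predsets = list(preds) if isinstance(preds, (list, tuple)) else [preds]

    txt_path = outdir / "report.txt"
    txt_path.write_text(report.text, encoding="utf-8")

    json_path = outdir / "report.json"
    record = report.to_dict()
    record["qfv"] = [q.to_dict() for q in qfvs]
    json_path.write_text(json.dumps(record, indent=2), encoding="utf-8")

    qfv_rows = []
    for q in qfvs:
        for roi, frac in q.fractions.items():
            qfv_rows.append(
                {
                    "scheme": q.scheme,
                    "roi": roi,
                    "fraction": frac,
                    "roi_voxels": q.roi_voxels.get(roi),
                    "lesion_voxels": q.lesion_voxels.get(roi),
                }
            )
    qfv_path = outdir / "qfv.csv"
    pd.DataFrame(
        qfv_rows, columns=["scheme", "roi", "fraction", "roi_voxels", "lesion_voxels"]
    ).to_csv(qfv_path, index=False)

    pred_rows = [row for ps in predsets for row in ps.to_records()]
    pred_path = outdir / "predictions.csv"
    pd.DataFrame(
        pred_rows if pred_rows else None,
        columns=["scheme", "roi", "label", "probability"] if not pred_rows else None,
    ).to_csv(pred_path, index=False)

    return {"text": txt_path, "json": json_path, "qfv": qfv_path,
            "predictions": pred_path}
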