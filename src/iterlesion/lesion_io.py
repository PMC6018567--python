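"""Lesion image I/O, binarization, overlap masks and ROI damage fractions.

Lesion images are 3D scalar volumes on a shared grid, either *fuzzy*
(continuous degree of abnormality in [0, 1] relative to healthy controls)
or *binary* (thresholded lesion / no-lesion).  All spatial bookkeeping is
voxel-index based; world coordinates are obtained through the NIfTI affine.
No resampling is performed anywhere: cohorts with mismatched grids are
rejected rather than interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "LesionImage",
    "OverlapMap",
    "AnalysisMask",
    "ROISet",
    "read_lesion_image",
    "write_image",
    "binarize",
    "lesion_volume",
    "overlap_map",
    "build_analysis_mask",
    "roi_damage_fraction",
]

#: default fuzzy-to-binary threshold U; a voxel is lesioned iff value > U
DEFAULT_BINARIZE_U = 0.3

_VALUE_TOL = 1e-6


@dataclass
class LesionImage:
    """One patient's abnormality map on the shared grid.

    Parameters
    ----------
    patient_id : str
        Opaque identifier, unique within a cohort.
    values : ndarray, shape (nx, ny, nz)
        Per-voxel abnormality in [0, 1].  For ``kind='binary'`` the values
        are exactly 0 or 1.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform in mm.
    kind : {'fuzzy', 'binary'}
    """

    patient_id: str
    values: np.ndarray
    affine: np.ndarray
    kind: str = "fuzzy"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"lesion image must be 3D, got {self.values.ndim}D "
                f"(patient {self.patient_id!r})"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.kind not in ("fuzzy", "binary"):
            raise ValueError(f"kind must be 'fuzzy' or 'binary', got {self.kind!r}")
        vmin, vmax = float(self.values.min()), float(self.values.max())
        if vmin < -_VALUE_TOL or vmax > 1.0 + _VALUE_TOL:
            raise ValueError(
                f"lesion values must lie in [0, 1]; got range "
                f"[{vmin:.6g}, {vmax:.6g}] (patient {self.patient_id!r})"
            )
        # snap tiny numerical excursions back into [0, 1]
        self.values = np.clip(self.values, 0.0, 1.0)
        if self.kind == "binary":
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0.0, 1.0))):
                raise ValueError(
                    f"binary image contains non-{{0,1}} values "
                    f"(patient {self.patient_id!r})"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the 3x3 affine block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class OverlapMap:
    """Per-voxel count of patients with a binary lesion."""

    counts: np.ndarray
    affine: np.ndarray
    n_patients: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.min() < 0 or self.counts.max() > self.n_patients:
            raise ValueError("overlap counts must lie in [0, n_patients]")


@dataclass
class AnalysisMask:
    """Search volume: voxels damaged in at least ``min_overlap`` patients."""

    include: np.ndarray
    min_overlap: int = 5

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())


@dataclass
class ROISet:
    """Labeled regions on the shared grid (0 = background, k = ROI k)."""

    labels: np.ndarray
    names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("ROI labels must be non-negative")
        present = set(np.unique(self.labels).tolist()) - {0}
        for k in self.names:
            if k not in present:
                raise ValueError(f"named label {k} absent from the label grid")

    @property
    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(k) for k in ids if k != 0]

    def is_empty(self) -> bool:
        return len(self.label_ids) == 0

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label

    def union_mask(self) -> np.ndarray:
        return self.labels > 0


def read_lesion_image(path: str | Path, kind: str = "fuzzy",
                      patient_id: str | None = None) -> LesionImage:
    """Load a 3D NIfTI lesion image.

    Raises on non-3D volumes and on voxel values outside [0, 1]
    (beyond a 1e-6 tolerance).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D: {path}")
    pid = patient_id if patient_id is not None else Path(path).name.split(".")[0]
    return LesionImage(patient_id=pid, values=np.asarray(data, dtype=np.float32),
                       affine=np.asarray(img.affine), kind=kind)


def write_image(grid: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3D grid as NIfTI.

    Integer grids (overlap counts, ROI labels) are stored as int32, so the
    round-trip is bit-exact; everything else is stored as float32.
    """
    grid = np.asarray(grid)
    if not np.all(np.isfinite(grid)):
        raise ValueError("grid contains non-finite values")
    if np.issubdtype(grid.dtype, np.integer) or grid.dtype == bool:
        out = grid.astype(np.int32)
    else:
        out = grid.astype(np.float32)
    nib.save(nib.Nifti1Image(out, np.asarray(affine, dtype=float)), str(path))


def binarize(img: LesionImage, u: float = DEFAULT_BINARIZE_U) -> LesionImage:
    """Threshold a fuzzy image: voxel lesioned iff value strictly exceeds u."""
    if img.kind != "fuzzy":
        raise ValueError("binarize expects a fuzzy image")
    if not (0.0 <= u < 1.0):
        raise ValueError(f"threshold u must lie in [0, 1), got {u}")
    vals = (img.values > u).astype(np.float32)
    return LesionImage(patient_id=img.patient_id, values=vals,
                       affine=img.affine, kind="binary")


def lesion_volume(img: LesionImage) -> float:
    """Lesion volume in cm^3 of a binary image (voxel count x voxel volume)."""
    if img.kind != "binary":
        raise ValueError("lesion_volume expects a binary image; binarize first")
    return float(img.values.sum()) * img.voxel_volume / 1000.0


def _binary_values(img: LesionImage, u: float) -> np.ndarray:
    if img.kind == "binary":
        return img.values
    return (img.values > u).astype(np.float32)


def overlap_map(cohort, u: float = DEFAULT_BINARIZE_U) -> OverlapMap:
    """Count, per voxel, how many patients have a binary lesion there.

    Always computed on binary lesion indicators; fuzzy images are
    thresholded at ``u`` on the fly.
    """
    patients = list(cohort.patients)
    if not patients:
        raise ValueError("empty cohort")
    shape = patients[0].lesion.shape
    affine = patients[0].lesion.affine
    counts = np.zeros(shape, dtype=np.int32)
    for p in patients:
        if p.lesion.shape != shape or not np.allclose(p.lesion.affine, affine):
            raise ValueError(f"grid mismatch for patient {p.patient_id!r}")
        counts += _binary_values(p.lesion, u).astype(np.int32)
    return OverlapMap(counts=counts, affine=affine, n_patients=len(patients))


def build_analysis_mask(om: OverlapMap, min_overlap: int = 5) -> AnalysisMask:
    """Inclusive search mask: voxels damaged in at least ``min_overlap`` patients."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    return AnalysisMask(include=om.counts >= min_overlap, min_overlap=min_overlap)


def roi_damage_fraction(img: LesionImage, roi_mask: np.ndarray) -> float:
    """Fraction of an ROI occupied by lesion for one patient.

    For binary images this is the lesioned proportion of the ROI; for fuzzy
    images it is the mean abnormality over the ROI (the natural continuous
    analogue).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    n = int(roi_mask.sum())
    if n == 0:
        raise ValueError("degenerate ROI: no voxels")
    return float(img.values[roi_mask].sum()) / n
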