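"""NIfTI volume containers and I/O.

Conventions used throughout the package:

* voxel indexing is 0-based; arrays are indexed ``data[i, j, k]`` in the
  order the NIfTI file stores them (no re-orientation is performed);
* world coordinates are obtained only through the 4x4 affine — no RAS
  assumption is made;
* binary masks are stored on disk as unsigned 8-bit, probability maps and
  intensity volumes as float32;
* deformation fields are stored as 4-D NIfTI with the displacement
  component on the last axis (shape ``(D, H, W, 3)``), in voxel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "LesionMask",
    "CasePair",
    "GridMismatchError",
    "load_volume",
    "load_case",
    "save_volume",
    "save_mask",
    "save_deformation_field",
    "load_deformation_field",
    "voxel_volume_mm3",
]

#: tolerance on voxel spacing (mm) when deciding two images share a grid
SPACING_TOL = 1e-4
#: tolerance on affine entries (float32 headers round-trip at ~1e-5)
AFFINE_TOL = 1e-3


class GridMismatchError(ValueError):
    """Two images that must share a voxel grid do not."""


@dataclass
class Volume3D:
    """A 3-D scalar image with voxel spacing (mm) and affine orientation."""

    data: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D.data must be 3-D, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume3D.data contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LesionMask:
    """A binary mask on a Volume3D grid, decomposable into 26-connected lesions."""

    data: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray
    connectivity: int = 26

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, got {vals[:10]}")
        self.data = arr.astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError(f"LesionMask.data must be 3-D, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def total_volume_mm3(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_mm3


@dataclass
class CasePair:
    """Baseline + follow-up volumes of one patient, sharing a single grid."""

    baseline: Volume3D
    followup: Volume3D
    brain_mask: Optional[LesionMask] = None
    gt_new_lesions: Optional[LesionMask] = None
    case_id: str = ""

    def __post_init__(self) -> None:
        check_same_grid(self.baseline, self.followup, names=("baseline", "followup"))
        for name in ("brain_mask", "gt_new_lesions"):
            m = getattr(self, name)
            if m is not None:
                check_same_grid(self.baseline, m, names=("baseline", name))

    @property
    def shape(self) -> tuple:
        return self.baseline.shape

    @property
    def spacing(self) -> np.ndarray:
        return self.baseline.spacing


def check_same_grid(a, b, names=("a", "b")) -> None:
    """Raise :class:`GridMismatchError` unless a and b share shape/spacing/affine."""
    if a.data.shape != b.data.shape:
        for axis in range(3):
            if a.data.shape[axis] != b.data.shape[axis]:
                raise GridMismatchError(
                    f"shape mismatch between {names[0]} and {names[1]} on axis {axis}: "
                    f"{a.data.shape} vs {b.data.shape}"
                )
    ds = np.abs(a.spacing - b.spacing)
    if np.any(ds > SPACING_TOL):
        axis = int(np.argmax(ds))
        raise GridMismatchError(
            f"spacing mismatch between {names[0]} and {names[1]} on axis {axis}: "
            f"{a.spacing} vs {b.spacing} (tol {SPACING_TOL} mm)"
        )
    if np.any(np.abs(a.affine - b.affine) > AFFINE_TOL):
        raise GridMismatchError(
            f"affine mismatch between {names[0]} and {names[1]} beyond tol {AFFINE_TOL}"
        )


def voxel_volume_mm3(spacing) -> float:
    """Volume of one voxel in mm^3 — the product of the spacing components."""
    return float(np.prod(np.asarray(spacing, dtype=float)))


def _load_nifti(path) -> tuple:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return data, img


def load_volume(path) -> Volume3D:
    """Load a 3-D NIfTI intensity volume. Rejects non-finite data."""
    data, img = _load_nifti(path)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite values")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return Volume3D(data=data.astype(np.float32), spacing=spacing, affine=img.affine)


def load_mask(path, reference: Optional[Volume3D] = None) -> LesionMask:
    """Load a binary mask, binarizing at > 0.5."""
    data, img = _load_nifti(path)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got shape {data.shape}")
    binar = (np.nan_to_num(data, nan=0.0) > 0.5).astype(np.uint8)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    mask = LesionMask(data=binar, spacing=spacing, affine=img.affine)
    if reference is not None:
        check_same_grid(reference, mask, names=("reference", str(path)))
    return mask


def load_case(
    baseline_path,
    followup_path,
    mask_path=None,
    gt_path=None,
    case_id: str = "",
) -> CasePair:
    """Load a two-timepoint case; all images must share one voxel grid."""
    baseline = load_volume(baseline_path)
    followup = load_volume(followup_path)
    brain_mask = load_mask(mask_path, reference=baseline) if mask_path else None
    gt = load_mask(gt_path, reference=baseline) if gt_path else None
    if not case_id:
        case_id = Path(baseline_path).name.split(".")[0]
    return CasePair(
        baseline=baseline,
        followup=followup,
        brain_mask=brain_mask,
        gt_new_lesions=gt,
        case_id=case_id,
    )


def save_volume(vol: Volume3D, path) -> None:
    """Write an intensity or probability volume as float32 NIfTI."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def save_mask(mask: LesionMask, reference: Volume3D, path) -> None:
    """Write a binary mask as uint8 NIfTI on the reference grid/affine."""
    check_same_grid(reference, mask, names=("reference", "mask"))
    img = nib.Nifti1Image(mask.data.astype(np.uint8), reference.affine)
    img.header.set_zooms(tuple(reference.spacing))
    nib.save(img, str(path))


def save_deformation_field(df: np.ndarray, reference: Volume3D, path) -> None:
    """Write a deformation field (D, H, W, 3), voxel units, as 4-D float32 NIfTI."""
    arr = np.asarray(df, dtype=np.float32)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"deformation field must have shape (D,H,W,3), got {arr.shape}")
    img = nib.Nifti1Image(arr, reference.affine)
    nib.save(img, str(path))


def load_deformation_field(path) -> np.ndarray:
    data, _ = _load_nifti(path)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: deformation field must be 4-D with last dim 3, got {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: deformation field contains non-finite values")
    return np.asarray(data, dtype=np.float32)
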