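"""Patch extraction regimes and whole-volume probability reconstruction.

Three regimes feed the cascade:

1. **lesion-centered** training patches — one patch per ground-truth lesion
   voxel, centered on it (origin clamped at borders).  Larger lesions thus
   contribute more samples, which is the intended implicit weighting;
2. **hard-example** patches — a dense lattice (default step 8) restricted
   to the union of the lesion area and the voxels the first stage got
   wrong;
3. **overlapped inference** patches — the same dense lattice over the whole
   volume (optionally within a brain mask), whose per-patch probabilities
   are averaged back into a full-volume map.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .volumes import CasePair, LesionMask, Volume3D, check_same_grid

__all__ = [
    "PatchSet",
    "CoverageError",
    "lesion_centered_patches",
    "grid_patches",
    "hard_example_region",
    "reconstruct_probability",
    "concatenate_patch_sets",
]


class CoverageError(ValueError):
    """The patch set leaves part of the volume uncovered."""


@dataclass
class PatchSet:
    """Co-located 3-D patches with their origin coordinates.

    ``baseline``/``followup``: (n, pd, ph, pw) float32;
    ``labels``: (n, pd, ph, pw) uint8 or None;
    ``dfs``: (n, pd, ph, pw, 3) float32 or None (displacement last axis);
    ``coords``: (n, 3) patch origins in the source grid (0-based).
    Origins may repeat: lesion-centered extraction keeps one sample per
    lesion voxel even when border clamping collapses origins.
    """

    coords: np.ndarray
    patch_shape: Tuple[int, int, int]
    baseline: np.ndarray
    followup: np.ndarray
    source_grid: Tuple[int, int, int]
    labels: Optional[np.ndarray] = None
    dfs: Optional[np.ndarray] = None
    case_ids: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 3)
        self.patch_shape = tuple(int(s) for s in self.patch_shape)
        self.source_grid = tuple(int(s) for s in self.source_grid)
        ps = np.asarray(self.patch_shape)
        grid = np.asarray(self.source_grid)
        if len(self.coords) and (np.any(self.coords < 0)
                                 or np.any(self.coords + ps > grid)):
            raise ValueError("every patch must lie fully inside the source grid")

    def __len__(self) -> int:
        return len(self.coords)

    def manifest(self) -> pd.DataFrame:
        """Patch bookkeeping table for debugging dumps."""
        df = pd.DataFrame(self.coords, columns=["i", "j", "k"])
        df["case_id"] = self.case_ids if self.case_ids is not None else ""
        if self.labels is not None:
            df["n_lesion_voxels"] = self.labels.reshape(len(self), -1).sum(axis=1)
        return df


def _extract(case: CasePair, origins: np.ndarray, patch_shape,
             external_df: Optional[np.ndarray] = None) -> PatchSet:
    pd_, ph, pw = patch_shape
    n = len(origins)
    base = np.empty((n, pd_, ph, pw), dtype=np.float32)
    fup = np.empty((n, pd_, ph, pw), dtype=np.float32)
    labels = None
    if case.gt_new_lesions is not None:
        labels = np.empty((n, pd_, ph, pw), dtype=np.uint8)
    dfs = None
    if external_df is not None:
        if external_df.shape != case.shape + (3,):
            raise ValueError(
                f"external df shape {external_df.shape} does not match case grid {case.shape}")
        dfs = np.empty((n, pd_, ph, pw, 3), dtype=np.float32)
    for idx, (i, j, k) in enumerate(origins):
        sl = (slice(i, i + pd_), slice(j, j + ph), slice(k, k + pw))
        base[idx] = case.baseline.data[sl]
        fup[idx] = case.followup.data[sl]
        if labels is not None:
            labels[idx] = case.gt_new_lesions.data[sl]
        if dfs is not None:
            dfs[idx] = external_df[sl]
    return PatchSet(
        coords=origins,
        patch_shape=tuple(patch_shape),
        baseline=base,
        followup=fup,
        labels=labels,
        dfs=dfs,
        case_ids=[case.case_id] * n,
        source_grid=tuple(case.shape),
    )


def lesion_centered_patches(case: CasePair, patch_shape=(32, 32, 32),
                            external_df: Optional[np.ndarray] = None,
                            jitter_rng: Optional[np.random.Generator] = None) -> PatchSet:
    """One patch per ground-truth lesion voxel, placed around it.

    By default the patch is centered on the voxel. With ``jitter_rng`` the
    voxel instead lands at a uniformly random position inside its patch;
    this keeps the lesion-voxel position uninformative, so a patch-wise
    network cannot latch onto the patch center as a shortcut and transfers
    to the arbitrary lesion/patch alignments of lattice inference.

    Origins are clamped so every patch fits inside the grid; duplicates
    after clamping are retained (one training sample per lesion voxel).
    An empty ground truth yields an empty set.
    """
    if case.gt_new_lesions is None:
        raise ValueError("case has no ground-truth new-lesion mask")
    ps = np.asarray(patch_shape, dtype=np.int64)
    grid = np.asarray(case.shape, dtype=np.int64)
    if np.any(ps > grid):
        raise ValueError(f"patch {tuple(ps)} larger than grid {tuple(grid)}")
    voxels = np.argwhere(case.gt_new_lesions.data > 0)
    if jitter_rng is None:
        offsets = ps // 2
    else:
        offsets = jitter_rng.integers(0, ps, size=voxels.shape)
    origins = np.clip(voxels - offsets, 0, grid - ps)
    return _extract(case, origins, patch_shape, external_df)


def _axis_origins(size: int, patch: int, step: int) -> List[int]:
    last = size - patch
    origins = list(range(0, last + 1, step))
    if origins[-1] != last:
        origins.append(last)  # clamped final origin so the far face is covered
    return origins


def grid_patches(case: CasePair, patch_shape=(32, 32, 32), step=(8, 8, 8),
                 region_mask: Optional[LesionMask] = None,
                 external_df: Optional[np.ndarray] = None) -> PatchSet:
    """Patches on a regular lattice covering the whole volume.

    Origins lie on {0, s, 2s, ...} per axis plus a final clamped origin so
    the far face is covered.  With ``region_mask``, only patches whose
    extent intersects the mask are kept.
    """
    ps = np.asarray(patch_shape, dtype=np.int64)
    step = np.asarray(step, dtype=np.int64)
    if np.any(step < 1):
        raise ValueError("step components must be >= 1")
    grid = np.asarray(case.shape, dtype=np.int64)
    if np.any(ps > grid):
        raise ValueError(f"patch {tuple(ps)} larger than grid {tuple(grid)}")
    axes = [_axis_origins(int(grid[a]), int(ps[a]), int(step[a])) for a in range(3)]
    origins = np.array(list(product(*axes)), dtype=np.int64)
    if region_mask is not None:
        check_same_grid(case.baseline, region_mask, names=("case", "region_mask"))
        keep = []
        for i, j, k in origins:
            if region_mask.data[i:i + ps[0], j:j + ps[1], k:k + ps[2]].any():
                keep.append((i, j, k))
        origins = np.array(keep, dtype=np.int64).reshape(-1, 3)
    return _extract(case, origins, tuple(int(s) for s in ps), external_df)


def hard_example_region(gt: LesionMask, pred: LesionMask) -> LesionMask:
    """Union of the lesion area and the voxels the prediction got wrong
    (false positives and false negatives) — the mining mask for stage 2."""
    check_same_grid(gt, pred, names=("gt", "pred"))
    disagree = np.logical_xor(gt.data > 0, pred.data > 0)
    region = np.logical_or(gt.data > 0, disagree)
    return LesionMask(data=region.astype(np.uint8), spacing=gt.spacing, affine=gt.affine)


def reconstruct_probability(coords: np.ndarray, patch_shape,
                            probabilities: np.ndarray,
                            source_grid, reference: Optional[Volume3D] = None) -> np.ndarray:
    """Average per-patch probabilities back into a full-volume map.

    Every voxel's value is the arithmetic mean of all covering patches'
    probabilities; voxels covered by no patch raise :class:`CoverageError`.
    """
    coords = np.asarray(coords, dtype=np.int64).reshape(-1, 3)
    probabilities = np.asarray(probabilities, dtype=np.float64)
    pd_, ph, pw = patch_shape
    if probabilities.shape != (len(coords), pd_, ph, pw):
        raise ValueError(
            f"probabilities shape {probabilities.shape} does not match "
            f"{len(coords)} patches of {tuple(patch_shape)}")
    acc = np.zeros(source_grid, dtype=np.float64)
    cnt = np.zeros(source_grid, dtype=np.int64)
    for idx, (i, j, k) in enumerate(coords):
        sl = (slice(i, i + pd_), slice(j, j + ph), slice(k, k + pw))
        acc[sl] += probabilities[idx]
        cnt[sl] += 1
    uncovered = int((cnt == 0).sum())
    if uncovered:
        raise CoverageError(f"{uncovered} voxels are covered by no patch")
    return np.clip(acc / cnt, 0.0, 1.0)


def concatenate_patch_sets(sets: Sequence[PatchSet]) -> PatchSet:
    """Pool patch sets from several cases (grids may differ; coords keep
    their per-case meaning through case_ids)."""
    sets = [s for s in sets if len(s)]
    if not sets:
        raise ValueError("no non-empty patch sets to concatenate")
    ps = sets[0].patch_shape
    if any(s.patch_shape != ps for s in sets):
        raise ValueError("patch shapes differ across sets")
    has_labels = all(s.labels is not None for s in sets)
    has_dfs = all(s.dfs is not None for s in sets)
    return PatchSet(
        coords=np.concatenate([s.coords for s in sets]),
        patch_shape=ps,
        baseline=np.concatenate([s.baseline for s in sets]),
        followup=np.concatenate([s.followup for s in sets]),
        labels=np.concatenate([s.labels for s in sets]) if has_labels else None,
        dfs=np.concatenate([s.dfs for s in sets]) if has_dfs else None,
        case_ids=sum((list(s.case_ids or [""] * len(s)) for s in sets), []),
        source_grid=sets[0].source_grid,
    )
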