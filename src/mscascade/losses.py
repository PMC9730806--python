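"""The combined supervised + unsupervised training loss.

The total loss is the sum of a supervised segmentation term and an
unsupervised registration term:

    L_total = w_seg * CE(Seg, GT)
            + w_sim * (1/N) * sum_i (F_i - B(DF)_i)^2
            + w_reg * sum_p ||grad DF(p)||^2

where F is the follow-up patch, B(DF) the baseline warped by the predicted
deformation field, Seg the predicted probability and GT the binary ground
truth.  The similarity term is a per-voxel mean while the regularization
term is a bare sum over voxels, so their natural scales differ by a factor
of the voxel count; the weights exist to balance them.

These are the reference (numpy) formulas; training uses the differentiable
twins in :mod:`mscascade.nn`, which agree with these to float precision
(asserted in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "LossWeights",
    "similarity_loss",
    "regularization_loss",
    "segmentation_loss",
    "total_loss",
]

CLIP_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    w_segmentation: float = 1.0
    w_similarity: float = 1.0
    w_regularization: float = 1.0

    def __post_init__(self) -> None:
        for w in (self.w_segmentation, self.w_similarity, self.w_regularization):
            if w < 0:
                raise ValueError("loss weights must be non-negative")
        if self.w_segmentation == self.w_similarity == self.w_regularization == 0:
            raise ValueError("at least one loss weight must be strictly positive")


def _check_shapes(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")


def similarity_loss(moved_baseline: np.ndarray, followup: np.ndarray) -> float:
    """Mean squared intensity difference between moved baseline and follow-up."""
    moved = np.asarray(moved_baseline, dtype=np.float64)
    fup = np.asarray(followup, dtype=np.float64)
    _check_shapes(moved, fup, "similarity_loss")
    return float(((fup - moved) ** 2).mean())


def regularization_loss(df: np.ndarray) -> float:
    """Sum over voxels of the squared spatial gradient of the deformation
    field, forward finite differences with zero gradient at the far face.

    ``df`` carries the displacement component on the last axis,
    shape (D, H, W, 3) (a single voxel, (1,1,1,3), has no neighbours and
    scores 0).
    """
    d = np.asarray(df, dtype=np.float64)
    if not np.all(np.isfinite(d)):
        raise ValueError("deformation field contains non-finite values")
    if d.ndim != 4 or d.shape[-1] != 3:
        raise ValueError(f"df must have shape (D,H,W,3), got {d.shape}")
    total = 0.0
    for axis in range(3):
        total += float((np.diff(d, axis=axis) ** 2).sum())
    return total


def segmentation_loss(prob: np.ndarray, gt: np.ndarray, eps: float = CLIP_EPS) -> float:
    """Mean voxelwise binary cross-entropy, probabilities clipped at eps."""
    p = np.asarray(prob, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    _check_shapes(p, g, "segmentation_loss")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0,1]")
    if not np.all(np.isin(np.unique(g), (0.0, 1.0))):
        raise ValueError("ground truth must be binary")
    pc = np.clip(p, eps, 1.0 - eps)
    return float(-(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean())


def total_loss(
    prob: np.ndarray,
    gt: np.ndarray,
    moved_baseline: Optional[np.ndarray],
    followup: Optional[np.ndarray],
    df: Optional[np.ndarray],
    weights: LossWeights = LossWeights(),
) -> Tuple[float, Dict[str, float]]:
    """Weighted sum of the three terms; returns (scalar, components).

    The registration terms are skipped (contributing 0) when the
    corresponding inputs are absent, as in the no-DF configuration.
    """
    ce = segmentation_loss(prob, gt)
    sim = similarity_loss(moved_baseline, followup) if moved_baseline is not None else 0.0
    reg = regularization_loss(df) if df is not None else 0.0
    total = (weights.w_segmentation * ce
             + weights.w_similarity * sim
             + weights.w_regularization * reg)
    return float(total), {"segmentation": ce, "similarity": sim, "regularization": reg}
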