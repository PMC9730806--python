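"""Voxel-level and lesion-level evaluation of new-lesion segmentations.

Two levels, as is standard for longitudinal lesion studies:

* **segmentation** — Dice score DSC = 2 TPs / (FNs + FPs + 2 TPs) over voxels;
* **detection** — lesions are 26-connected components; with lesion counts
  TP/FP/FN, F1 = 2 TP / (FN + FP + 2 TP), PPVL = TP / (TP + FP),
  SensL = TP / (TP + FN).

A ground-truth lesion counts as detected (TP) when the prediction covers
strictly more than ``min_overlap_fraction`` of its voxels; a predicted
component is a false positive only when it overlaps no ground-truth lesion
at all.  The matching rule is configurable and any reported result should
state it.

Cases with no true new lesions are excluded from the detection and
segmentation means and instead contribute their falsely predicted lesion
volume (mm^3) to the VolTested measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LesionMask, check_same_grid

__all__ = [
    "VoxelCounts",
    "LesionCounts",
    "CaseReport",
    "dice",
    "voxel_counts",
    "match_lesions",
    "detection_scores",
    "vol_tested",
    "evaluate_case",
    "evaluate_cohort",
]

DEFAULT_MIN_OVERLAP = 0.1
_STRUCTURE = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclass(frozen=True)
class VoxelCounts:
    tp_s: int
    fp_s: int
    fn_s: int


@dataclass(frozen=True)
class LesionCounts:
    tp: int
    fp: int
    fn: int
    matching_rule: float = DEFAULT_MIN_OVERLAP


@dataclass
class CaseReport:
    case_id: str
    dsc: float
    dsc_defined: bool
    f1: float
    ppvl: float
    sensl: float
    voltested_mm3: float
    n_gt_lesions: int
    n_pred_lesions: int


def voxel_counts(pred: LesionMask, gt: LesionMask) -> VoxelCounts:
    check_same_grid(pred, gt, names=("pred", "gt"))
    p = pred.data > 0
    g = gt.data > 0
    return VoxelCounts(
        tp_s=int(np.sum(p & g)),
        fp_s=int(np.sum(p & ~g)),
        fn_s=int(np.sum(~p & g)),
    )


def dice(pred: LesionMask, gt: LesionMask) -> float:
    """Voxel-level Dice; two empty masks score 1 by convention (the
    prediction is vacuously perfect — flagged in :class:`CaseReport`)."""
    c = voxel_counts(pred, gt)
    denom = c.fn_s + c.fp_s + 2 * c.tp_s
    if denom == 0:
        return 1.0
    return 2.0 * c.tp_s / denom


def _components(mask: LesionMask) -> Tuple[np.ndarray, int]:
    return ndimage.label(mask.data > 0, structure=_STRUCTURE)


def match_lesions(pred: LesionMask, gt: LesionMask,
                  min_overlap_fraction: float = DEFAULT_MIN_OVERLAP) -> LesionCounts:
    """Lesion-wise matching by component overlap.

    TP: ground-truth lesions covered by prediction on > min_overlap_fraction
    of their voxels; FN: the remaining ground-truth lesions; FP: predicted
    components that touch no ground-truth lesion at all.
    """
    if not (0.0 <= min_overlap_fraction < 1.0):
        raise ValueError("min_overlap_fraction must lie in [0,1)")
    check_same_grid(pred, gt, names=("pred", "gt"))
    gt_lab, n_gt = _components(gt)
    pred_lab, n_pred = _components(pred)
    pred_bin = pred.data > 0

    tp = 0
    for lesion in range(1, n_gt + 1):
        support = gt_lab == lesion
        frac = np.sum(pred_bin & support) / np.sum(support)
        if frac > min_overlap_fraction:
            tp += 1
    fn = n_gt - tp

    fp = 0
    gt_bin = gt.data > 0
    for comp in range(1, n_pred + 1):
        if not np.any(gt_bin & (pred_lab == comp)):
            fp += 1
    return LesionCounts(tp=tp, fp=fp, fn=fn, matching_rule=min_overlap_fraction)


def detection_scores(counts: LesionCounts) -> Tuple[float, float, float]:
    """(F1, PPVL, SensL) from lesion counts; undefined ratios are 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    f1 = 2.0 * tp / (fn + fp + 2 * tp) if (fn + fp + tp) > 0 else 0.0
    ppvl = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    sensl = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return f1, ppvl, sensl


def vol_tested(pred: LesionMask, spacing=None) -> float:
    """Falsely predicted lesion volume (mm^3) on a case with no true new
    lesions — every predicted voxel is false by definition."""
    sp = np.asarray(spacing if spacing is not None else pred.spacing, dtype=float)
    return float(pred.data.sum()) * float(np.prod(sp))


def evaluate_case(pred: LesionMask, gt: LesionMask,
                  min_overlap_fraction: float = DEFAULT_MIN_OVERLAP,
                  case_id: str = "") -> CaseReport:
    _, n_gt = _components(gt)
    _, n_pred = _components(pred)
    has_gt = n_gt > 0
    dsc = dice(pred, gt)
    if has_gt:
        counts = match_lesions(pred, gt, min_overlap_fraction)
        f1, ppvl, sensl = detection_scores(counts)
        volt = float("nan")
    else:
        if gt.data.sum() > 0:  # pragma: no cover - guarded by n_gt
            raise ValueError("vol_tested route requires an empty ground truth")
        f1 = ppvl = sensl = float("nan")
        volt = vol_tested(pred)
    return CaseReport(
        case_id=case_id,
        dsc=dsc,
        dsc_defined=bool(has_gt or n_pred > 0),
        f1=f1, ppvl=ppvl, sensl=sensl,
        voltested_mm3=volt,
        n_gt_lesions=n_gt,
        n_pred_lesions=n_pred,
    )


def evaluate_cohort(cases: Sequence[Tuple[LesionMask, LesionMask]],
                    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP,
                    case_ids: Optional[Sequence[str]] = None) -> Dict:
    """Per-case table plus cohort summary.

    Detection/segmentation means (+- SD) are taken over cases with at least
    one true lesion only; VolTested is the mean falsely predicted volume
    over the remaining (lesion-free) cases.
    """
    if len(cases) == 0:
        raise ValueError("evaluate_cohort needs at least one case")
    if case_ids is None:
        case_ids = [f"case_{i:03d}" for i in range(len(cases))]
    reports = [
        evaluate_case(pred, gt, min_overlap_fraction, cid)
        for (pred, gt), cid in zip(cases, case_ids)
    ]
    table = pd.DataFrame([r.__dict__ for r in reports])

    with_gt = table[table.n_gt_lesions > 0]
    without_gt = table[table.n_gt_lesions == 0]
    summary: Dict = {
        "n_cases": len(table),
        "n_cases_with_lesions": int(len(with_gt)),
        "n_cases_without_lesions": int(len(without_gt)),
        "matching_rule_min_overlap": min_overlap_fraction,
    }
    for metric in ("dsc", "f1", "ppvl", "sensl"):
        if len(with_gt):
            vals = with_gt[metric].to_numpy(dtype=float)
            summary[f"{metric}_mean"] = float(np.mean(vals))
            summary[f"{metric}_std"] = float(np.std(vals))
            summary[f"{metric}_mean_percent"] = float(100.0 * np.mean(vals))
    if len(without_gt):
        summary["voltested_mean_mm3"] = float(without_gt.voltested_mm3.mean())
    return {"per_case": table, "summary": summary}
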