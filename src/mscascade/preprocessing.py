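"""Intensity standardization and a minimal brain mask.

Longitudinal FLAIR pairs from different scanners have incompatible intensity
scales; piecewise-linear histogram matching (Nyul-style landmark
standardization) maps every image onto one learned standard scale so that a
fixed network sees comparable inputs.  Images are assumed already
bias-field-corrected and skull-stripped (or maskable by the trivial
threshold mask below).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .volumes import LesionMask, Volume3D

__all__ = [
    "DEFAULT_LANDMARK_PERCENTILES",
    "DegenerateIntensityError",
    "IntensityStandardizer",
    "fit_standardizer",
    "normalize",
    "trivial_brain_mask",
]

#: deciles plus the 1st/99th percentile — the canonical landmark set
DEFAULT_LANDMARK_PERCENTILES = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)

#: the learned standard scale is affinely pinned to this range
STANDARD_RANGE = (0.0, 100.0)


class DegenerateIntensityError(ValueError):
    """Raised when a volume's intensity distribution is too flat to standardize."""


def _foreground_values(vol: Volume3D, mask: Optional[LesionMask]) -> np.ndarray:
    """In-mask voxels when a mask is given, else strictly positive voxels.

    Background zeros would otherwise dominate the histogram and drag every
    low landmark to zero.
    """
    if mask is not None:
        vals = vol.data[mask.data > 0]
    else:
        vals = vol.data[vol.data > 0]
        if vals.size == 0:  # all-nonpositive image: fall back to everything
            vals = vol.data.ravel()
    return np.asarray(vals, dtype=np.float64)


def _volume_landmarks(vals: np.ndarray, percentiles: Sequence[float]) -> np.ndarray:
    if vals.size == 0:
        raise DegenerateIntensityError("no foreground voxels to compute percentiles from")
    lm = np.percentile(vals, percentiles)
    if np.any(np.diff(lm) <= 0):
        raise DegenerateIntensityError(
            "landmark percentiles are not strictly increasing; "
            "intensity distribution is degenerate (e.g., constant volume)"
        )
    return lm


@dataclass
class IntensityStandardizer:
    """Piecewise-linear intensity standardizer on histogram landmarks."""

    landmark_percentiles: tuple = DEFAULT_LANDMARK_PERCENTILES
    standard_scale_landmarks: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.landmark_percentiles, dtype=float)
        if p.ndim != 1 or len(p) < 2:
            raise ValueError("need at least two landmark percentiles")
        if np.any(np.diff(p) <= 0) or p[0] <= 0 or p[-1] >= 100:
            raise ValueError("landmark percentiles must be strictly increasing within (0,100)")
        self.landmark_percentiles = tuple(p)
        if self.standard_scale_landmarks is not None:
            self.standard_scale_landmarks = np.asarray(self.standard_scale_landmarks, float)

    @property
    def trained(self) -> bool:
        return self.standard_scale_landmarks is not None

    # -- persistence --------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "landmark_percentiles": list(self.landmark_percentiles),
            "standard_scale_landmarks": (
                None if self.standard_scale_landmarks is None
                else [float(v) for v in self.standard_scale_landmarks]
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "IntensityStandardizer":
        with open(path) as fh:
            payload = json.load(fh)
        lm = payload["standard_scale_landmarks"]
        return cls(
            landmark_percentiles=tuple(payload["landmark_percentiles"]),
            standard_scale_landmarks=None if lm is None else np.asarray(lm, float),
        )


def fit_standardizer(
    volumes: Sequence[Volume3D],
    masks: Optional[Sequence[Optional[LesionMask]]] = None,
    landmark_percentiles: Sequence[float] = DEFAULT_LANDMARK_PERCENTILES,
) -> IntensityStandardizer:
    """Learn the standard intensity scale from a set of training volumes.

    Each volume's landmark percentiles are mapped affinely so its outermost
    landmarks land on the fixed standard range; the standard scale is the
    per-landmark mean of these mapped vectors.
    """
    if len(volumes) == 0:
        raise ValueError("need at least one training volume")
    if masks is None:
        masks = [None] * len(volumes)
    lo, hi = STANDARD_RANGE
    mapped = []
    for vol, msk in zip(volumes, masks):
        lm = _volume_landmarks(_foreground_values(vol, msk), landmark_percentiles)
        scale = (hi - lo) / (lm[-1] - lm[0])
        mapped.append(lo + (lm - lm[0]) * scale)
    standard = np.mean(np.stack(mapped, axis=0), axis=0)
    if np.any(np.diff(standard) <= 0):
        raise DegenerateIntensityError("learned standard scale is not strictly increasing")
    return IntensityStandardizer(
        landmark_percentiles=tuple(landmark_percentiles),
        standard_scale_landmarks=standard,
    )


def _piecewise_linear(values: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Monotone piecewise-linear map sending src[i] -> dst[i], linear
    extrapolation beyond the outermost landmarks."""
    out = np.interp(values, src, dst)
    lo_slope = (dst[1] - dst[0]) / (src[1] - src[0])
    hi_slope = (dst[-1] - dst[-2]) / (src[-1] - src[-2])
    below = values < src[0]
    above = values > src[-1]
    out[below] = dst[0] + (values[below] - src[0]) * lo_slope
    out[above] = dst[-1] + (values[above] - src[-1]) * hi_slope
    return out


def normalize(
    vol: Volume3D,
    std: IntensityStandardizer,
    mask: Optional[LesionMask] = None,
) -> Volume3D:
    """Map a volume onto the learned standard scale.

    The volume's own landmark intensities are sent exactly to the standard
    landmarks; intermediate intensities are interpolated linearly and
    intensities beyond the outermost landmarks are extrapolated linearly.
    The voxel grid is unchanged.
    """
    if not std.trained:
        raise RuntimeError("standardizer has not been fitted")
    lm = _volume_landmarks(_foreground_values(vol, mask), std.landmark_percentiles)
    out = _piecewise_linear(
        vol.data.astype(np.float64).ravel(), lm, std.standard_scale_landmarks
    ).reshape(vol.data.shape)
    return Volume3D(data=out.astype(np.float32), spacing=vol.spacing, affine=vol.affine)


def normalize_case(case, std: IntensityStandardizer):
    """Normalize both timepoints of a case with one standardizer."""
    from .volumes import CasePair

    return CasePair(
        baseline=normalize(case.baseline, std, case.brain_mask),
        followup=normalize(case.followup, std, case.brain_mask),
        brain_mask=case.brain_mask,
        gt_new_lesions=case.gt_new_lesions,
        case_id=case.case_id,
    )


def trivial_brain_mask(vol: Volume3D, threshold_fraction: float = 0.25) -> LesionMask:
    """Threshold mask: voxels above threshold_fraction x P99, largest
    26-connected component only, holes filled.

    A deliberately simple stand-in for a full skull-stripping step; inputs
    are expected to be brain-dominated volumes on a dark background.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must lie in (0,1)")
    data = vol.data
    if np.ptp(data) == 0:
        raise DegenerateIntensityError("constant volume has no maskable structure")
    thr = threshold_fraction * np.percentile(data, 99)
    binary = data > thr
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        raise DegenerateIntensityError("threshold leaves no voxels above it")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = 1 + int(np.argmax(sizes))
    mask = ndimage.binary_fill_holes(labels == largest)
    return LesionMask(data=mask.astype(np.uint8), spacing=vol.spacing, affine=vol.affine)
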