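"""Two-timepoint phantom generator with known deformation and new lesions.

Emulates the data regime of a longitudinal FLAIR study: an ellipsoidal
"brain" with smooth internal structure at baseline; a follow-up that is the
same anatomy warped by a smooth random residual deformation (the part rigid
pre-registration leaves behind), globally shifted in intensity
(scanner/session effect), carrying a small number of small bright new
lesions absent at baseline, with independent voxel noise at each timepoint.

Every nuisance is switchable, the true deformation field and lesion mask
are returned, and generation is bit-reproducible from the seed — so every
downstream stage can be tested without access to restricted clinical data.
Optionally, bright "distractor" blobs present at *both* timepoints can be
added to make false positives likely for a sensitivity-tuned first stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .networks import warp
from .volumes import CasePair, LesionMask, Volume3D

__all__ = [
    "PhantomSpec",
    "SyntheticCase",
    "PlacementError",
    "generate_case",
    "generate_cohort",
    "write_case",
]


class PlacementError(RuntimeError):
    """Lesions could not be placed without overlap within the retry budget."""


@dataclass(frozen=True)
class PhantomSpec:
    """Conditions of one synthetic two-timepoint case.

    Intensities are in standardized units (tissue ~50 on a 0-100 scale);
    new lesions are additive bright ellipsoids (hyperintense, as on FLAIR).
    """

    shape: Tuple[int, int, int] = (64, 64, 64)
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_new_lesions: int = 3
    lesion_radius_range_mm: Tuple[float, float] = (1.5, 3.0)
    lesion_contrast: float = 30.0
    deformation_amplitude_vox: float = 1.0
    deformation_smoothness_vox: float = 6.0
    intensity_shift: float = 5.0
    noise_sigma: float = 2.0
    n_distractors: int = 0
    distractor_contrast: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "lesion_radius_range_mm",
                           tuple(float(r) for r in self.lesion_radius_range_mm))
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise ValueError("shape must be 3 integers >= 16")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")
        if self.n_new_lesions < 0 or self.n_distractors < 0:
            raise ValueError("lesion/distractor counts must be non-negative")
        rmin, rmax = self.lesion_radius_range_mm
        if not (0 < rmin <= rmax):
            raise ValueError("lesion radius range must satisfy 0 < min <= max")
        if any(rmin / sp < 1.0 for sp in self.spacing_mm):
            raise ValueError("minimum lesion radius must span >= 1 voxel on every axis")
        if self.lesion_contrast <= 0:
            raise ValueError("lesion_contrast must be positive")
        if self.deformation_amplitude_vox < 0 or self.deformation_smoothness_vox <= 0:
            raise ValueError("deformation amplitude must be >= 0 and smoothness > 0")
        # keep correspondence local relative to the 32-voxel reference patch
        if self.deformation_amplitude_vox >= min(8.0, min(self.shape) / 4):
            raise ValueError("deformation amplitude too large to keep correspondence local")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SyntheticCase:
    pair: CasePair
    true_df: np.ndarray  # (D, H, W, 3), voxel units
    spec: PhantomSpec


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _ellipsoid_support(shape, center, semiaxes_vox) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes_vox))
    return q <= 1.0


def _brain_phantom(spec: PhantomSpec, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Smooth tissue phantom: bright ellipsoidal brain with internal
    structure and a darker central 'ventricle'. Returns (image, support)."""
    shape = spec.shape
    center = [(s - 1) / 2 for s in shape]
    brain = _ellipsoid_support(shape, center, [0.42 * s for s in shape])
    ventricle = _ellipsoid_support(shape, center, [0.10 * s for s in shape])
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), 4.0)
    texture *= 8.0 / max(np.abs(texture).max(), 1e-9)
    img = np.zeros(shape, dtype=np.float64)
    img[brain] = 50.0
    img += texture * brain
    img[ventricle] -= 20.0
    return img, brain


def _smooth_random_df(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """White noise per component, Gaussian-smoothed, scaled so the largest
    displacement magnitude equals the requested amplitude."""
    shape = spec.shape
    df = np.zeros(shape + (3,), dtype=np.float64)
    if spec.deformation_amplitude_vox == 0:
        return df
    for c in range(3):
        df[..., c] = ndimage.gaussian_filter(
            rng.standard_normal(shape), spec.deformation_smoothness_vox)
    mag = np.sqrt((df ** 2).sum(axis=-1)).max()
    df *= spec.deformation_amplitude_vox / max(mag, 1e-12)
    return df


def _place_blobs(spec: PhantomSpec, rng: np.random.Generator, n_blobs: int,
                 allowed: np.ndarray, occupied: np.ndarray,
                 min_volume_mm3: float = 3.0, max_tries: int = 200) -> List[np.ndarray]:
    """Draw non-overlapping ellipsoidal supports inside ``allowed``,
    keeping >= 2 voxels separation (so 26-connected components stay
    distinct) and voxelized volume above the post-filter floor."""
    voxvol = float(np.prod(spec.spacing_mm))
    rmin, rmax = spec.lesion_radius_range_mm
    structure = np.ones((3, 3, 3), dtype=bool)
    blobs: List[np.ndarray] = []
    candidates = np.argwhere(allowed)
    if n_blobs > 0 and len(candidates) == 0:
        raise PlacementError("no interior voxels available for placement")
    for _ in range(n_blobs):
        for attempt in range(max_tries):
            center = candidates[rng.integers(len(candidates))]
            r_mm = rng.uniform(rmin, rmax)
            semi = np.array([
                max(r_mm * rng.uniform(0.8, 1.2) / sp, 1.0) for sp in spec.spacing_mm
            ])
            support = _ellipsoid_support(spec.shape, center, semi)
            if support.sum() * voxvol <= min_volume_mm3:
                continue
            if not np.all(allowed[support]):
                continue
            grown = ndimage.binary_dilation(support, structure=structure)
            if np.any(occupied & grown):
                continue
            blobs.append(support)
            occupied |= grown
            break
        else:
            raise PlacementError(
                f"could not place blob {len(blobs) + 1}/{n_blobs} after {max_tries} tries")
    return blobs


def generate_case(spec: PhantomSpec) -> SyntheticCase:
    """Generate one two-timepoint phantom case.

    baseline = tissue phantom (+ distractors) + noise;
    followup = baseline anatomy warped by a smooth random true DF,
    + global intensity shift + new lesions + independent noise;
    the ground truth marks exactly the inserted lesion voxels.
    """
    rng = np.random.default_rng(int(spec.seed))
    clean, brain = _brain_phantom(spec, rng)
    true_df = _smooth_random_df(spec, rng)

    # placement region: inside the brain, away from its edge and the ventricle
    interior = ndimage.binary_erosion(brain, iterations=4)
    occupied = np.zeros(spec.shape, dtype=bool)

    distractors = _place_blobs(spec, rng, spec.n_distractors, interior, occupied)
    for blob in distractors:
        clean[blob] += spec.distractor_contrast  # present at both timepoints

    followup_clean = warp(clean, true_df)

    lesions = _place_blobs(spec, rng, spec.n_new_lesions, interior, occupied)
    gt = np.zeros(spec.shape, dtype=np.uint8)
    for blob in lesions:
        followup_clean[blob] += spec.lesion_contrast
        gt[blob] = 1

    noise_b = rng.standard_normal(spec.shape) * spec.noise_sigma
    noise_f = rng.standard_normal(spec.shape) * spec.noise_sigma
    baseline = clean + noise_b
    followup = followup_clean + spec.intensity_shift + noise_f

    aff = _affine(spec.spacing_mm)
    sp = np.asarray(spec.spacing_mm, dtype=float)
    pair = CasePair(
        baseline=Volume3D(baseline.astype(np.float32), sp, aff),
        followup=Volume3D(followup.astype(np.float32), sp, aff),
        brain_mask=LesionMask(brain.astype(np.uint8), sp, aff),
        gt_new_lesions=LesionMask(gt, sp, aff),
        case_id=f"phantom_{spec.seed}",
    )
    return SyntheticCase(pair=pair, true_df=true_df.astype(np.float32), spec=spec)


def generate_cohort(spec_template: PhantomSpec, n_cases: int, seed: int,
                    zero_lesion_fraction: float = 0.25) -> List[SyntheticCase]:
    """Generate a cohort with per-case seeds derived from ``seed``.

    A fixed fraction of the cases (round(fraction * n), chosen at random
    but reproducibly) is generated with no new lesions, mirroring cohorts
    in which some patients show no disease activity between timepoints.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not (0.0 <= zero_lesion_fraction <= 1.0):
        raise ValueError("zero_lesion_fraction must lie in [0,1]")
    rng = np.random.default_rng(int(seed))
    n_zero = int(round(zero_lesion_fraction * n_cases))
    zero_idx = set(rng.choice(n_cases, size=n_zero, replace=False).tolist())
    cases = []
    for i in range(n_cases):
        case_seed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % (2 ** 31))
        n_lesions = 0 if i in zero_idx else spec_template.n_new_lesions
        spec = replace(spec_template, seed=case_seed, n_new_lesions=n_lesions)
        case = generate_case(spec)
        case.pair.case_id = f"case_{i:03d}"
        cases.append(case)
    return cases


def write_case(case: SyntheticCase, out_dir) -> None:
    """Write baseline/followup/GT/true-DF NIfTIs for one case."""
    from .volumes import save_deformation_field, save_mask, save_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cid = case.pair.case_id
    save_volume(case.pair.baseline, out / f"{cid}_baseline.nii.gz")
    save_volume(case.pair.followup, out / f"{cid}_followup.nii.gz")
    save_mask(case.pair.gt_new_lesions, case.pair.baseline, out / f"{cid}_gt.nii.gz")
    save_deformation_field(case.true_df, case.pair.baseline, out / f"{cid}_truedf.nii.gz")


def cohort_manifest(cases: List[SyntheticCase]) -> pd.DataFrame:
    rows = []
    for case in cases:
        gt = case.pair.gt_new_lesions
        labels, n = ndimage.label(gt.data, structure=np.ones((3, 3, 3)))
        vols = ndimage.sum_labels(gt.data.astype(float), labels,
                                  index=np.arange(1, n + 1)) * gt.voxel_volume_mm3
        rows.append({
            "case_id": case.pair.case_id,
            "seed": case.spec.seed,
            "n_lesions": n,
            "lesion_volumes_mm3": ";".join(f"{v:.1f}" for v in vols),
        })
    return pd.DataFrame(rows)
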