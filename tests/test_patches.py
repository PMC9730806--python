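"""Patch extraction lattices, hard-example mining and map reconstruction."""

import numpy as np
import pytest

from mscascade.patches import (CoverageError, PatchSet, grid_patches,
                               hard_example_region, lesion_centered_patches,
                               reconstruct_probability)

from conftest import make_case, make_mask


def _case_with_gt(shape=(64, 64, 64), lesion_voxels=(), rng=None):
    rng = rng or np.random.default_rng(0)
    gt = np.zeros(shape, dtype=np.uint8)
    for v in lesion_voxels:
        gt[v] = 1
    return make_case(rng.random(shape), rng.random(shape), gt)


def test_one_patch_per_lesion_voxel():
    voxels = [(10, 10, 10), (10, 10, 11), (40, 20, 30), (5, 60, 60), (63, 63, 63)]
    case = _case_with_gt(lesion_voxels=voxels)
    ps = lesion_centered_patches(case, (32, 32, 32))
    assert len(ps) == 5


def test_empty_gt_gives_empty_set():
    case = _case_with_gt()
    assert len(lesion_centered_patches(case, (32, 32, 32))) == 0


def test_corner_voxel_origin_clamped_to_zero():
    case = _case_with_gt(lesion_voxels=[(0, 0, 0)])
    ps = lesion_centered_patches(case, (32, 32, 32))
    np.testing.assert_array_equal(ps.coords[0], (0, 0, 0))


def test_origin_clamping_matches_bruteforce_bounds():
    """Clamped center-origin rule against explicit bound enumeration."""
    shape = (40, 40, 40)
    rng = np.random.default_rng(3)
    voxels = [tuple(v) for v in rng.integers(0, 40, size=(20, 3))]
    case = _case_with_gt(shape, voxels, rng)
    ps = lesion_centered_patches(case, (32, 32, 32))
    for voxel, origin in zip(np.argwhere(case.gt_new_lesions.data), ps.coords):
        for a in range(3):
            lo = max(0, min(voxel[a] - 16, shape[a] - 32))
            assert origin[a] == lo
        # the selected voxel lies inside its patch
        assert np.all(origin <= voxel) and np.all(voxel < origin + 32)


def test_jittered_placement_keeps_voxel_inside_patch():
    rng = np.random.default_rng(7)
    voxels = [tuple(v) for v in rng.integers(0, 64, size=(30, 3))]
    case = _case_with_gt((64, 64, 64), voxels, rng)
    ps = lesion_centered_patches(case, (16, 16, 16),
                                 jitter_rng=np.random.default_rng(5))
    assert len(ps) == len(np.argwhere(case.gt_new_lesions.data))
    for voxel, origin in zip(np.argwhere(case.gt_new_lesions.data), ps.coords):
        assert np.all(origin <= voxel) and np.all(voxel < origin + 16)


def test_single_patch_when_patch_equals_grid():
    case = _case_with_gt((32, 32, 32))
    ps = grid_patches(case, (32, 32, 32), (8, 8, 8))
    assert len(ps) == 1
    np.testing.assert_array_equal(ps.coords[0], (0, 0, 0))


def test_lattice_origins_match_enumeration():
    case = _case_with_gt((40, 40, 40))
    ps = grid_patches(case, (32, 32, 32), (8, 8, 8))
    expected = {(i, j, k) for i in (0, 8) for j in (0, 8) for k in (0, 8)}
    assert {tuple(c) for c in ps.coords} == expected


def test_far_face_clamped_origin_added():
    case = _case_with_gt((35, 35, 35))
    ps = grid_patches(case, (32, 32, 32), (8, 8, 8))
    # lattice {0} plus clamped 3 per axis
    assert {tuple(c) for c in ps.coords} == {(i, j, k) for i in (0, 3)
                                             for j in (0, 3) for k in (0, 3)}


def test_region_mask_filter_matches_bruteforce():
    case = _case_with_gt((64, 64, 64))
    region = np.zeros((64, 64, 64), dtype=np.uint8)
    region[:8, :8, :8] = 1
    mask = make_mask(region)
    ps = grid_patches(case, (32, 32, 32), (8, 8, 8), region_mask=mask)
    full = grid_patches(case, (32, 32, 32), (8, 8, 8))
    expected = {tuple(c) for c in full.coords
                if region[c[0]:c[0] + 32, c[1]:c[1] + 32, c[2]:c[2] + 32].any()}
    assert {tuple(c) for c in ps.coords} == expected
    assert len(ps) < len(full)


def test_patch_larger_than_grid_errors():
    case = _case_with_gt((16, 16, 16))
    with pytest.raises(ValueError, match="larger"):
        grid_patches(case, (32, 32, 32), (8, 8, 8))


def test_full_coverage_when_step_leq_patch(rng):
    for shape, patch, step in (((40, 40, 40), 32, 8), ((37, 41, 45), 16, 16),
                               ((64, 64, 64), 16, 8)):
        case = _case_with_gt(shape, rng=rng)
        ps = grid_patches(case, (patch,) * 3, (step,) * 3)
        cover = np.zeros(shape, dtype=int)
        for i, j, k in ps.coords:
            cover[i:i + patch, j:j + patch, k:k + patch] += 1
        assert cover.min() >= 1


def test_hard_example_region_is_gt_union_errors():
    gt = np.zeros((16, 16, 16), dtype=np.uint8)
    gt[2:4, 2:4, 2:4] = 1
    pred = np.zeros_like(gt)
    pred[10:12, 10:12, 10:12] = 1    # false-positive blob
    region = hard_example_region(make_mask(gt), make_mask(pred))
    expected = np.logical_or(gt, pred)
    np.testing.assert_array_equal(region.data.astype(bool), expected)


def test_hard_example_region_perfect_prediction_is_gt():
    gt = np.zeros((8, 8, 8), dtype=np.uint8)
    gt[1:3, 1:3, 1:3] = 1
    region = hard_example_region(make_mask(gt), make_mask(gt))
    np.testing.assert_array_equal(region.data, gt)


def test_hard_example_region_empty_prediction_is_gt():
    gt = np.zeros((8, 8, 8), dtype=np.uint8)
    gt[4:6, 4:6, 4:6] = 1
    region = hard_example_region(make_mask(gt), make_mask(np.zeros_like(gt)))
    np.testing.assert_array_equal(region.data, gt)


def test_reconstruct_constant_predictor():
    coords = np.array([(i, j, k) for i in (0, 8) for j in (0, 8) for k in (0, 8)])
    probs = np.full((8, 32, 32, 32), 0.7)
    out = reconstruct_probability(coords, (32, 32, 32), probs, (40, 40, 40))
    np.testing.assert_allclose(out, 0.7)


def test_reconstruct_count_weighted_mean_on_overlap():
    coords = np.array([(0, 0, 0), (0, 0, 2)])
    probs = np.stack([np.full((4, 4, 4), 0.2), np.full((4, 4, 4), 0.6)])
    out = reconstruct_probability(coords, (4, 4, 4), probs, (4, 4, 6))
    np.testing.assert_allclose(out[:, :, :2], 0.2)
    np.testing.assert_allclose(out[:, :, 2:4], 0.4)   # overlap: mean of 0.2, 0.6
    np.testing.assert_allclose(out[:, :, 4:], 0.6)


def test_reconstruct_uncovered_voxels_error():
    coords = np.array([(0, 0, 0)])
    probs = np.full((1, 4, 4, 4), 0.5)
    with pytest.raises(CoverageError, match="48"):
        reconstruct_probability(coords, (4, 4, 4), probs, (4, 4, 7))


def test_identity_predictor_roundtrip(rng):
    """Extract -> per-patch 'probability' = followup patch -> reconstruct
    reproduces the followup volume wherever coverage >= 1."""
    data = rng.random((40, 40, 40)).astype(np.float32)
    case = make_case(np.zeros_like(data), data)
    ps = grid_patches(case, (16, 16, 16), (8, 8, 8))
    out = reconstruct_probability(ps.coords, (16, 16, 16),
                                  ps.followup.astype(np.float64), (40, 40, 40))
    np.testing.assert_allclose(out, data, atol=1e-6)


def test_patchset_rejects_out_of_bounds_origin():
    with pytest.raises(ValueError, match="inside"):
        PatchSet(coords=np.array([(30, 0, 0)]), patch_shape=(8, 8, 8),
                 baseline=np.zeros((1, 8, 8, 8)), followup=np.zeros((1, 8, 8, 8)),
                 source_grid=(32, 32, 32))
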