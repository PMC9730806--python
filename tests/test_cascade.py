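"""Cascade orchestration: post-filter, early stopping, stage inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscascade import nn
from mscascade.cascade import (EarlyStopping, InsufficientDataError,
                               ProbabilityMap, TrainingConfig, binarize,
                               predict_cascade, predict_stage, train_stage)
from mscascade.networks import NetworkConfig
from mscascade.patches import PatchSet

from conftest import make_case

TINY_NET = dict(base_channels=(2, 4, 8, 16), patch_shape=(16, 16, 16))


# ------------------------------------------------------------- binarize

def _pmap(data, spacing=(1.0, 1.0, 1.0)):
    return ProbabilityMap(np.asarray(data, dtype=float), np.asarray(spacing),
                          np.diag(list(spacing) + [1.0]))


def test_two_voxel_blob_removed_at_1mm3():
    prob = np.zeros((8, 8, 8))
    prob[1, 1, 1:3] = 0.9
    assert binarize(_pmap(prob)).data.sum() == 0


def test_four_voxel_blob_retained_at_1mm3():
    prob = np.zeros((8, 8, 8))
    prob[1, 1, 1:5] = 0.9
    assert binarize(_pmap(prob)).data.sum() == 4


def test_component_filter_matches_bruteforce_sizes():
    prob = np.zeros((32, 32, 32))
    prob[1, 1, 1:3] = 0.8        # 2 voxels -> removed
    prob[10, 10:15, 10] = 0.8    # 5 voxels -> kept
    prob[20:24, 20:25, 20:25] = 0.8  # 100 voxels -> kept
    out = binarize(_pmap(prob))
    assert out.data.sum() == 105
    assert out.data[1, 1, 1] == 0


def test_anisotropic_spacing_changes_the_cut():
    prob = np.zeros((8, 8, 8))
    prob[1, 1, 1:5] = 0.9        # 4 voxels
    fine = binarize(_pmap(prob, spacing=(0.5, 0.5, 0.5)))   # 0.5 mm^3 < 3
    assert fine.data.sum() == 0
    coarse = binarize(_pmap(prob, spacing=(1.0, 1.0, 1.2)))  # 4.8 mm^3 >= 3
    assert coarse.data.sum() == 4


def test_threshold_strictly_greater():
    prob = np.zeros((8, 8, 8))
    prob[0, 0, :6] = 0.5
    assert binarize(_pmap(prob), threshold=0.5).data.sum() == 0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.2, 0.8), st.floats(0.2, 0.8))
def test_binarize_monotone_in_threshold(seed, t1, t2):
    rng = np.random.default_rng(seed)
    prob = _pmap(rng.random((12, 12, 12)))
    lo, hi = sorted((t1, t2))
    assert binarize(prob, hi, 0.0).data.sum() <= binarize(prob, lo, 0.0).data.sum()


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 10.0), st.floats(0.0, 10.0))
def test_binarize_monotone_in_min_volume(seed, v1, v2):
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    prob = _pmap(rng.random((12, 12, 12)) * 0.9)
    lo, hi = sorted((v1, v2))
    s = np.ones((3, 3, 3))
    n_hi = ndimage.label(binarize(prob, 0.5, hi).data, structure=s)[1]
    n_lo = ndimage.label(binarize(prob, 0.5, lo).data, structure=s)[1]
    assert n_hi <= n_lo


# -------------------------------------------------------- early stopping

def test_early_stopping_constant_loss_stops_after_patience_plus_one():
    stopper = EarlyStopping(patience=2)
    assert not stopper.update(1.0)   # epoch 1: first value is the best
    assert not stopper.update(1.0)   # epoch 2: stall 1
    assert stopper.update(1.0)       # epoch 3: stall 2 -> stop
    assert stopper.best_epoch == 1


def test_early_stopping_resets_on_strict_improvement():
    stopper = EarlyStopping(patience=2)
    assert not stopper.update(1.0)
    assert not stopper.update(1.0)
    assert not stopper.update(0.5)   # improvement resets the stall counter
    assert not stopper.update(0.5)
    assert stopper.update(0.5)
    assert stopper.best_epoch == 3


# ------------------------------------------------------- stage training

def _toy_patch_set(rng, n=8, s=16, n_cases=2):
    labels = (rng.random((n, s, s, s)) < 0.02).astype(np.uint8)
    return PatchSet(
        coords=np.zeros((n, 3), dtype=int),
        patch_shape=(s, s, s),
        baseline=rng.random((n, s, s, s)).astype(np.float32) * 50,
        followup=rng.random((n, s, s, s)).astype(np.float32) * 50,
        labels=labels,
        case_ids=[f"c{i % n_cases}" for i in range(n)],
        source_grid=(s, s, s),
    )


def test_train_stage_single_patch_insufficient(rng):
    ps = _toy_patch_set(rng, n=1)
    cfg = TrainingConfig(max_epochs=2, patience=1, network=NetworkConfig(**TINY_NET))
    with pytest.raises(InsufficientDataError):
        train_stage(ps, cfg)


def test_train_stage_best_epoch_no_worse_than_first(rng):
    ps = _toy_patch_set(rng, n=8)
    cfg = TrainingConfig(max_epochs=3, patience=2, batch_size=4,
                         network=NetworkConfig(**TINY_NET), seed=0)
    _, hist = train_stage(ps, cfg)
    assert hist.attrs["best_val"] <= hist.val_total.iloc[0] + 1e-12
    assert {"total", "segmentation", "similarity", "regularization"} <= set(hist.columns)


def test_train_stage_deterministic(rng):
    ps = _toy_patch_set(rng, n=6)
    cfg = TrainingConfig(max_epochs=2, patience=1, batch_size=4,
                         network=NetworkConfig(**TINY_NET), seed=5)
    m1, h1 = train_stage(ps, cfg)
    m2, h2 = train_stage(ps, cfg)
    for a, b in zip(m1.params(), m2.params()):
        np.testing.assert_array_equal(a.data, b.data)
    assert h1.val_total.tolist() == h2.val_total.tolist()


# ------------------------------------------------------ stage inference

class _ConstantModel:
    """Duck-typed stand-in whose probability output is a constant."""

    def __init__(self, value, patch_shape=(16, 16, 16)):
        self.value = value
        self.cfg = NetworkConfig(base_channels=(2, 4, 8, 16), patch_shape=patch_shape)

    def forward(self, baseline, followup, external_df=None, with_logits=False):
        shape = (baseline.data.shape[0], 1) + tuple(self.cfg.patch_shape)
        prob = nn.Tensor(np.full(shape, self.value, dtype=np.float32))
        return prob, None, None


def test_predict_stage_constant_model(rng):
    case = make_case(rng.random((32, 32, 32)), rng.random((32, 32, 32)))
    pm = predict_stage(_ConstantModel(0.3), case, step=(8, 8, 8))
    np.testing.assert_allclose(pm.data, 0.3, atol=1e-6)
    assert pm.data.min() >= 0 and pm.data.max() <= 1


def test_predict_stage_repeatable(rng):
    from mscascade.networks import build_joint_model

    case = make_case(rng.random((32, 32, 32)), rng.random((32, 32, 32)))
    model = build_joint_model(NetworkConfig(**TINY_NET), seed=4)
    a = predict_stage(model, case, step=(16, 16, 16))
    b = predict_stage(model, case, step=(16, 16, 16))
    np.testing.assert_array_equal(a.data, b.data)


def test_cascade_average_of_equal_stages_is_stage(rng):
    from mscascade.cascade import CascadeModel

    case = make_case(rng.random((32, 32, 32)), rng.random((32, 32, 32)))
    cfg = TrainingConfig(max_epochs=2, patience=1, network=NetworkConfig(**TINY_NET))
    m = CascadeModel(fcnn1=_ConstantModel(0.8), fcnn2=_ConstantModel(0.4),
                     config=cfg, standardizer=None)
    final, mask = predict_cascade(m, case)
    np.testing.assert_allclose(final.data, 0.6, atol=1e-6)   # (0.8+0.4)/2
    assert mask.data.all()   # 0.6 > 0.5 everywhere, one huge component


def test_probability_map_clipped_to_unit_interval():
    pm = _pmap(np.linspace(-0.2, 1.3, 27).reshape(3, 3, 3))
    assert pm.data.min() >= 0.0 and pm.data.max() <= 1.0


def test_training_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(max_epochs=5, patience=5)
    with pytest.raises(ValueError):
        TrainingConfig(validation_fraction=1.5)
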