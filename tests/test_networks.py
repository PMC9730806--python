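"""Network builders, the spatial transformer, and the joint composition."""

import numpy as np
import pytest

from mscascade import nn
from mscascade.networks import (NetworkConfig, build_joint_model,
                                build_registration_net,
                                build_segmentation_net, load_model,
                                save_model, warp)

SMALL = dict(base_channels=(2, 4, 8, 16), patch_shape=(16, 16, 16))


def _rand_pair(rng, n=1, s=16):
    b = nn.Tensor(rng.standard_normal((n, 1, s, s, s)).astype(np.float32))
    f = nn.Tensor(rng.standard_normal((n, 1, s, s, s)).astype(np.float32))
    return b, f


def test_patch_shape_must_divide_16():
    with pytest.raises(ValueError, match="divisible"):
        NetworkConfig(patch_shape=(24, 24, 24))


def test_registration_net_output_shape(rng):
    net = build_registration_net(NetworkConfig(**SMALL), seed=0)
    b, f = _rand_pair(rng)
    out = net(nn.concat([b, f]))
    assert out.data.shape == (1, 3, 16, 16, 16)


def test_segmentation_probability_in_unit_interval(rng):
    net = build_segmentation_net(NetworkConfig(**SMALL), seed=0)
    b, f = _rand_pair(rng)
    df = nn.Tensor(rng.standard_normal((1, 3, 16, 16, 16)).astype(np.float32))
    prob = net(nn.concat([b, f]), df)
    assert prob.data.shape == (1, 1, 16, 16, 16)
    assert prob.data.min() >= 0.0 and prob.data.max() <= 1.0


def test_nodf_variant_needs_no_field(rng):
    cfg = NetworkConfig(df_source="none", **SMALL)
    model = build_joint_model(cfg, seed=0)
    b, f = _rand_pair(rng)
    prob, df, moved = model.forward(b, f)
    assert df is None and moved is None
    assert prob.data.shape == (1, 1, 16, 16, 16)


def test_external_df_variant(rng):
    cfg = NetworkConfig(df_source="external", **SMALL)
    model = build_joint_model(cfg, seed=0)
    b, f = _rand_pair(rng)
    ext = nn.Tensor(rng.standard_normal((1, 3, 16, 16, 16)).astype(np.float32))
    prob, df, moved = model.forward(b, f, external_df=ext)
    assert prob.data.shape == (1, 1, 16, 16, 16)
    assert df is ext and moved is None
    with pytest.raises(ValueError, match="external"):
        model.forward(b, f)


def test_joint_model_three_outputs(rng):
    model = build_joint_model(NetworkConfig(**SMALL), seed=0)
    b, f = _rand_pair(rng)
    prob, df, moved = model.forward(b, f)
    assert prob.data.shape == (1, 1, 16, 16, 16)
    assert df.data.shape == (1, 3, 16, 16, 16)
    assert moved.data.shape == (1, 1, 16, 16, 16)


def test_unet_parameter_count_matches_between_paths():
    """Registration and segmentation-branch U-Nets are architecturally
    identical, so they differ only by the input-channel count of the first
    convolution (and the registration head)."""
    cfg = NetworkConfig(**SMALL)
    reg = build_registration_net(cfg, seed=0)
    seg = build_segmentation_net(cfg, seed=0)
    n_reg_unet = sum(p.data.size for p in reg.unet.params())
    n_seg_b1 = sum(p.data.size for p in seg.branch_images.params())
    assert n_reg_unet == n_seg_b1  # both read 2 channels
    n_seg_b2 = sum(p.data.size for p in seg.branch_df.params())
    k3 = cfg.kernel_size ** 3
    c1 = cfg.base_channels[0]
    assert n_seg_b2 - n_seg_b1 == (3 - 2) * c1 * k3  # one extra input channel


def test_builders_deterministic_given_seed(rng):
    m1 = build_joint_model(NetworkConfig(**SMALL), seed=11)
    m2 = build_joint_model(NetworkConfig(**SMALL), seed=11)
    for a, b in zip(m1.params(), m2.params()):
        np.testing.assert_array_equal(a.data, b.data)
    m3 = build_joint_model(NetworkConfig(**SMALL), seed=12)
    assert any(not np.array_equal(a.data, c.data)
               for a, c in zip(m1.params(), m3.params()))


def test_one_gradient_step_decreases_loss(rng):
    model = build_joint_model(NetworkConfig(**SMALL), seed=5)
    b, f = _rand_pair(rng, n=2)
    lab = (rng.random((2, 1, 16, 16, 16)) < 0.05).astype(np.float64)

    def compute():
        prob, df, moved, logits = model.forward(b, f, with_logits=True)
        return nn.add(nn.bce_with_logits_loss(logits, lab),
                      nn.add(nn.mse_loss(moved, f),
                             nn.scale(nn.smoothness_loss(df), 1e-4)))

    opt = nn.Adam(model.params(), lr=1e-3)
    before = compute()
    before_val = before.item()
    before.backward()
    opt.step()
    assert compute().item() < before_val


def test_checkpoint_roundtrip(tmp_path, rng):
    model = build_joint_model(NetworkConfig(**SMALL), seed=3)
    save_model(model, tmp_path / "net")
    back = load_model(tmp_path / "net")
    assert back.cfg == model.cfg
    b, f = _rand_pair(rng)
    p1, _, _ = model.forward(b, f)
    p2, _, _ = back.forward(b, f)
    np.testing.assert_array_equal(p1.data, p2.data)


# ------------------------------------------------------------------ warp

def test_warp_zero_field_is_identity(rng):
    img = rng.standard_normal((8, 8, 8))
    out = warp(img, np.zeros((8, 8, 8, 3)))
    np.testing.assert_allclose(out, img, atol=1e-6)


def test_warp_integer_shift_matches_roll(rng):
    img = rng.standard_normal((10, 10, 10))
    df = np.zeros((10, 10, 10, 3))
    df[..., 2] = 1.0   # sample one voxel ahead in z
    out = warp(img, df)
    np.testing.assert_allclose(out[:, :, :-1], img[:, :, 1:], atol=1e-6)


def test_warp_fractional_shift_exact_on_linear_image():
    """Trilinear interpolation reproduces linear functions exactly."""
    z = np.arange(8, dtype=float)
    img = np.broadcast_to(z, (8, 8, 8)).copy()
    df = np.zeros((8, 8, 8, 3))
    df[..., 2] = 0.5
    out = warp(img, df)
    np.testing.assert_allclose(out[:, :, :-1],
                               img[:, :, :-1] + 0.5, atol=1e-5)


def test_warp_constant_image_invariant(rng):
    img = np.full((8, 8, 8), 3.25)
    df = rng.standard_normal((8, 8, 8, 3)) * 5
    np.testing.assert_allclose(warp(img, df), 3.25, atol=1e-6)


def test_warp_shape_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        warp(np.zeros((8, 8, 8)), np.zeros((8, 8, 7, 3)))
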