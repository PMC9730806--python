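"""Registration and segmentation networks and their end-to-end composition.

The model is a pair of 3-D patch U-Nets trained jointly:

* a **registration U-Net** that, from a stacked (baseline, follow-up) patch,
  predicts the dense deformation field (DF) aligning baseline to follow-up
  space, with a differentiable spatial transformer warping the baseline by
  the predicted DF (so the similarity loss can drive it);
* a **two-branch segmentation U-Net** whose first branch reads the
  (baseline, follow-up) pair and whose second branch reads the DF; branch
  outputs are concatenated and classified voxelwise into "new lesion"
  probability.

Both U-Nets share one architecture: four downsampling/upsampling steps,
core element (CE) blocks of two same-padded 3x3x3 convolutions, channel
concatenation skips, max pooling down and nearest-neighbour upsampling up.
The registration path uses LeakyReLU activations so displacements can be
signed; the segmentation path uses plain ReLU.

Displacements are expressed in voxel units: the spatial transformer samples
on the voxel grid directly. For anisotropic data, multiply by the spacing
vector to obtain mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "NetworkConfig",
    "UNet3D",
    "JointModel",
    "build_registration_net",
    "build_segmentation_net",
    "build_joint_model",
    "warp",
    "save_model",
    "load_model",
]

DF_SOURCES = ("learned", "external", "none")


@dataclass
class NetworkConfig:
    """Architecture hyperparameters shared by both cascade stages."""

    base_channels: Tuple[int, int, int, int] = (64, 128, 256, 512)
    kernel_size: int = 3
    leaky_slope: float = 0.2
    df_source: str = "learned"
    patch_shape: Tuple[int, int, int] = (32, 32, 32)

    def __post_init__(self) -> None:
        self.base_channels = tuple(int(c) for c in self.base_channels)
        if len(self.base_channels) != 4 or any(c < 1 for c in self.base_channels):
            raise ValueError("base_channels must be 4 positive integers")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if not (0.0 < self.leaky_slope < 1.0):
            raise ValueError("leaky_slope must lie in (0,1)")
        if self.df_source not in DF_SOURCES:
            raise ValueError(f"df_source must be one of {DF_SOURCES}")
        self.patch_shape = tuple(int(s) for s in self.patch_shape)
        if len(self.patch_shape) != 3:
            raise ValueError("patch_shape must have 3 components")
        for s in self.patch_shape:
            if s % 16 != 0 or s < 16:
                raise ValueError(
                    f"patch_shape {self.patch_shape} must be divisible by 2^4 = 16 "
                    "(four downsampling steps)"
                )

    @property
    def use_registration_branch(self) -> bool:
        return self.df_source == "learned"


def _he_init(rng: np.random.Generator, shape, fan_in: int, gain: float = 2.0):
    std = np.sqrt(gain / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class _Conv:
    def __init__(self, rng, c_in, c_out, k, init_std=None, bias_init=0.0):
        fan_in = c_in * k ** 3
        if init_std is None:
            w = _he_init(rng, (c_out, c_in, k, k, k), fan_in)
        else:
            w = rng.normal(0.0, init_std, size=(c_out, c_in, k, k, k)).astype(np.float32)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.full(c_out, bias_init, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return nn.conv3d(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class _CEBlock:
    """Core element: two same-padded convolutions, each followed by a
    (leaky) rectifier."""

    def __init__(self, rng, c_in, c_out, k, slope):
        self.conv1 = _Conv(rng, c_in, c_out, k)
        self.conv2 = _Conv(rng, c_out, c_out, k)
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        x = nn.leaky_relu(self.conv1(x), self.slope)
        return nn.leaky_relu(self.conv2(x), self.slope)

    def params(self):
        return self.conv1.params() + self.conv2.params()


class UNet3D:
    """Four-level 3-D U-Net producing a full-resolution feature map with
    ``base_channels[0]`` channels.

    Contracting CE channels: (c1, c2, c3, c4); expansive: (c4, c3, c2, c1);
    a CE bottleneck at 1/16 resolution; skips by channel concatenation.
    """

    def __init__(self, rng: np.random.Generator, in_channels: int,
                 cfg: NetworkConfig, slope: float):
        c1, c2, c3, c4 = cfg.base_channels
        k = cfg.kernel_size
        self.enc = [
            _CEBlock(rng, in_channels, c1, k, slope),
            _CEBlock(rng, c1, c2, k, slope),
            _CEBlock(rng, c2, c3, k, slope),
            _CEBlock(rng, c3, c4, k, slope),
        ]
        self.bottom = _CEBlock(rng, c4, c4, k, slope)
        self.dec = [
            _CEBlock(rng, c4 + c4, c4, k, slope),
            _CEBlock(rng, c4 + c3, c3, k, slope),
            _CEBlock(rng, c3 + c2, c2, k, slope),
            _CEBlock(rng, c2 + c1, c1, k, slope),
        ]

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = nn.maxpool2(x)
        x = self.bottom(x)
        for block, skip in zip(self.dec, reversed(skips)):
            x = nn.concat([nn.upsample2(x), skip])
            x = block(x)
        return x

    def params(self):
        out = []
        for block in self.enc + [self.bottom] + self.dec:
            out += block.params()
        return out


class RegistrationNet:
    """U-Net mapping a 2-channel (baseline, follow-up) patch to a 3-channel
    displacement patch; linear output head with small init so training
    starts near the identity warp."""

    def __init__(self, rng, cfg: NetworkConfig):
        self.unet = UNet3D(rng, 2, cfg, cfg.leaky_slope)
        self.head = _Conv(rng, cfg.base_channels[0], 3, 1, init_std=1e-3)

    def __call__(self, x: Tensor) -> Tensor:
        return self.head(self.unet(x))

    def params(self):
        return self.unet.params() + self.head.params()


class SegmentationNet:
    """Two-branch segmentation network; plain-ReLU U-Nets with independent
    weights, outputs concatenated and classified by a 1x1x1 convolution
    with logistic output."""

    def __init__(self, rng, cfg: NetworkConfig):
        c1 = cfg.base_channels[0]
        # head bias starts at the logit of a ~1% lesion prior so the first
        # epochs refine lesion features instead of burning down background
        prior_logit = -4.6
        self.branch_images = UNet3D(rng, 2, cfg, slope=0.0)
        if cfg.df_source == "none":
            self.branch_df = None
            self.head = _Conv(rng, c1, 1, 1, bias_init=prior_logit)
        else:
            self.branch_df = UNet3D(rng, 3, cfg, slope=0.0)
            self.head = _Conv(rng, 2 * c1, 1, 1, bias_init=prior_logit)

    def logits(self, images: Tensor, df: Optional[Tensor]) -> Tensor:
        feat = self.branch_images(images)
        if self.branch_df is not None:
            if df is None:
                raise ValueError("this configuration requires a deformation-field input")
            feat = nn.concat([feat, self.branch_df(df)])
        return self.head(feat)

    def __call__(self, images: Tensor, df: Optional[Tensor]) -> Tensor:
        return nn.sigmoid(self.logits(images, df))

    def params(self):
        out = self.branch_images.params()
        if self.branch_df is not None:
            out += self.branch_df.params()
        return out + self.head.params()


class JointModel:
    """End-to-end composition: registration subnet (optional), spatial
    transformer, and the two-branch segmentation subnet.

    forward() returns (probability, df, moved_baseline); the last two are
    None when ``df_source="none"``, and df is the external input when
    ``df_source="external"``.
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.registration = RegistrationNet(rng, cfg) if cfg.use_registration_branch else None
        self.segmentation = SegmentationNet(rng, cfg)

    def forward(self, baseline: Tensor, followup: Tensor,
                external_df: Optional[Tensor] = None, with_logits: bool = False):
        """baseline/followup: (N, 1, D, H, W); external_df: (N, 3, D, H, W).

        With ``with_logits=True`` the pre-sigmoid logits are returned as a
        fourth element (the training loss is computed on them)."""
        images = nn.concat([baseline, followup])
        df = moved = None
        if self.cfg.df_source == "learned":
            df = self.registration(images)
            moved = nn.warp_tensor(baseline, df)
        elif self.cfg.df_source == "external":
            if external_df is None:
                raise ValueError("df_source='external' requires an external_df input")
            df = external_df
        logits = self.segmentation.logits(images, df)
        prob = nn.sigmoid(logits)
        if with_logits:
            return prob, df, moved, logits
        return prob, df, moved

    __call__ = forward

    def params(self) -> List[Tensor]:
        out = []
        if self.registration is not None:
            out += self.registration.params()
        return out + self.segmentation.params()

    # -- checkpointing -------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model has {len(params)} parameters")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.data.shape}")
            p.data = arr

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))


def build_registration_net(cfg: NetworkConfig, seed: int = 0) -> RegistrationNet:
    rng = np.random.default_rng(int(seed))
    return RegistrationNet(rng, cfg)


def build_segmentation_net(cfg: NetworkConfig, seed: int = 0) -> SegmentationNet:
    rng = np.random.default_rng(int(seed))
    return SegmentationNet(rng, cfg)


def build_joint_model(cfg: NetworkConfig, seed: int = 0) -> JointModel:
    return JointModel(cfg, seed=seed)


def warp(image: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Warp a 3-D image by a voxel-displacement field.

    Output voxel x takes the trilinear sample of ``image`` at ``x + df(x)``;
    out-of-bounds positions clamp to the border.  ``df`` has shape
    ``image.shape + (3,)`` with the displacement component on the last axis.
    """
    return nn.trilinear_sample(image, df)


def save_model(model: JointModel, path) -> None:
    """Write weights (.npz) plus a JSON sidecar with the full NetworkConfig."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = {"config": asdict(model.cfg), "seed": model.seed}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> JointModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = NetworkConfig(**sidecar["config"])
    model = JointModel(cfg, seed=sidecar.get("seed", 0))
    with np.load(path.with_suffix(".npz")) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return model
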