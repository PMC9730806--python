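"""A compact reverse-mode autodiff engine on numpy, sized to 3-D patch U-Nets.

Implements exactly the primitives the registration/segmentation networks
need: same-padded 3-D convolution, 2x max-pooling, nearest-neighbour
upsampling, channel concatenation, (leaky) rectifiers, the logistic output,
a differentiable trilinear warp, and the three training losses.  Tensors
carry ``(N, C, D, H, W)`` float32 arrays; losses are float64 scalars.

Gradient correctness for every primitive is established by central-
finite-difference checks in the test suite.
"""

from __future__ import annotations

import itertools
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "conv3d",
    "leaky_relu",
    "maxpool2",
    "upsample2",
    "concat",
    "sigmoid",
    "warp_tensor",
    "mse_loss",
    "bce_loss",
    "bce_with_logits_loss",
    "smoothness_loss",
    "add",
    "scale",
    "Adam",
    "trilinear_sample",
]

BCE_EPS = 1e-7


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "requires_grad")

    def __init__(self, data, parents: Sequence[Tuple["Tensor", Callable]] = (),
                 requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self._parents = tuple(parents)
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from a scalar loss through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() starts from a scalar")
        topo: List[Tensor] = []
        seen = set()

        def visit(node: Tensor) -> None:
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for parent, _ in it:
                    if id(parent) not in seen:
                        seen.add(id(parent))
                        stack.append((parent, iter(parent._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data, dtype=np.float64)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, grad_fn in node._parents:
                contrib = grad_fn(node.grad)
                if contrib is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros(parent.data.shape, dtype=np.float64)
                parent.grad += contrib

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)


# ---------------------------------------------------------------- conv3d

def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 3-D convolution, stride 1.

    x: (N, Ci, D, H, W); w: (Co, Ci, k, k, k); b: (Co,).

    Computed as a sum over the k^3 kernel offsets of one (Co, Ci) x
    (Ci, N*D*H*W) GEMM each — faster in numpy than materializing the full
    im2col matrix.
    """
    k = w.data.shape[-1]
    p = k // 2
    N, Ci, D, H, W = x.data.shape
    Co = w.data.shape[0]
    if w.data.shape[1] != Ci:
        raise ValueError(f"conv3d: input has {Ci} channels, kernel expects {w.data.shape[1]}")
    offsets = list(itertools.product(range(k), repeat=3))
    nvox = N * D * H * W
    # channel-first padded copy so every offset slice reshapes cheaply
    xp = np.zeros((Ci, N, D + 2 * p, H + 2 * p, W + 2 * p), dtype=np.float32)
    xp[:, :, p:p + D, p:p + H, p:p + W] = x.data.transpose(1, 0, 2, 3, 4)
    wmat = w.data.reshape(Co, Ci * k ** 3)

    def build_cols():
        cols = np.empty((Ci, k ** 3, nvox), dtype=np.float32)
        for o, (i, j, l) in enumerate(offsets):
            cols[:, o].reshape(Ci, N, D, H, W)[:] = xp[:, :, i:i + D, j:j + H, l:l + W]
        return cols.reshape(Ci * k ** 3, nvox)

    out = (wmat @ build_cols()).reshape(Co, N, D, H, W).transpose(1, 0, 2, 3, 4)
    out = out + b.data[None, :, None, None, None]

    def _gmat(g):
        return np.ascontiguousarray(
            g.transpose(1, 0, 2, 3, 4), dtype=np.float32).reshape(Co, nvox)

    def grad_x(g):
        dcols = (wmat.T @ _gmat(g)).reshape(Ci, k ** 3, N, D, H, W)
        dxp = np.zeros_like(xp, dtype=np.float32)
        for o, (i, j, l) in enumerate(offsets):
            dxp[:, :, i:i + D, j:j + H, l:l + W] += dcols[:, o]
        return dxp[:, :, p:p + D, p:p + H, p:p + W].transpose(1, 0, 2, 3, 4).astype(np.float64)

    def grad_w(g):
        return (_gmat(g) @ build_cols().T).reshape(Co, Ci, k, k, k).astype(np.float64)

    def grad_b(g):
        return g.sum(axis=(0, 2, 3, 4))

    return Tensor(out.astype(np.float32),
                  parents=((x, grad_x), (w, grad_w), (b, grad_b)))


# ------------------------------------------------------------ activations

def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, slope * x.data)

    def grad_x(g):
        return g * np.where(mask, 1.0, slope)

    return Tensor(out.astype(np.float32), parents=((x, grad_x),))


def sigmoid(x: Tensor) -> Tensor:
    xd = np.clip(x.data.astype(np.float64), -60.0, 60.0)
    out = 1.0 / (1.0 + np.exp(-xd))

    def grad_x(g):
        return g * out * (1.0 - out)

    return Tensor(out.astype(np.float32), parents=((x, grad_x),))


# -------------------------------------------------------- pooling / resize

def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2; spatial dims must be even."""
    N, C, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(D, H, W)}")
    D2, H2, W2 = D // 2, H // 2, W // 2
    xr = (x.data.reshape(N, C, D2, 2, H2, 2, W2, 2)
          .transpose(0, 1, 2, 4, 6, 3, 5, 7)
          .reshape(N, C, D2, H2, W2, 8))
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def grad_x(g):
        gz = np.zeros((N, C, D2, H2, W2, 8), dtype=np.float64)
        np.put_along_axis(gz, idx[..., None], g[..., None], axis=-1)
        return (gz.reshape(N, C, D2, H2, W2, 2, 2, 2)
                .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                .reshape(N, C, D, H, W))

    return Tensor(np.ascontiguousarray(out), parents=((x, grad_x),))


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling in all three spatial dims."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
    N, C, D, H, W = x.data.shape

    def grad_x(g):
        return g.reshape(N, C, D, 2, H, 2, W, 2).sum(axis=(3, 5, 7))

    return Tensor(out, parents=((x, grad_x),))


def concat(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    parents = []
    for i, t in enumerate(tensors):
        lo, hi = offsets[i], offsets[i + 1]
        parents.append((t, lambda g, lo=lo, hi=hi: g[:, lo:hi]))
    return Tensor(out, parents=parents)


# ------------------------------------------------------------------ warp

def _corner_data(df_data: np.ndarray, shape: Tuple[int, int, int]):
    """Shared geometry for the trilinear warp: clamped sample positions,
    floor corners, fractional weights and the in-bounds mask per axis."""
    N = df_data.shape[0]
    D, H, W = shape
    base = np.stack(np.meshgrid(
        np.arange(D), np.arange(H), np.arange(W), indexing="ij"), axis=0)
    pos_raw = df_data.astype(np.float64) + base[None]
    pos = np.empty_like(pos_raw)
    unclamped = np.empty(pos_raw.shape, dtype=bool)
    for a, size in enumerate((D, H, W)):
        pos[:, a] = np.clip(pos_raw[:, a], 0.0, size - 1.0)
        unclamped[:, a] = (pos_raw[:, a] > 0.0) & (pos_raw[:, a] < size - 1.0)
    f = np.empty((N, 3) + shape, dtype=np.int64)
    t = np.empty((N, 3) + shape, dtype=np.float64)
    for a, size in enumerate((D, H, W)):
        fa = np.clip(np.floor(pos[:, a]).astype(np.int64), 0, max(size - 2, 0))
        f[:, a] = fa
        t[:, a] = pos[:, a] - fa
    return f, t, unclamped


def warp_tensor(image: Tensor, df: Tensor) -> Tensor:
    """Differentiable trilinear warp of a batched image by a displacement field.

    image: (N, C, D, H, W); df: (N, 3, D, H, W), displacements in voxels.
    Output voxel x samples image at x + df(x); out-of-bounds positions are
    clamped to the border.
    """
    if image.data.shape[0] != df.data.shape[0] or image.data.shape[2:] != df.data.shape[2:]:
        raise ValueError(
            f"warp: image {image.data.shape} and df {df.data.shape} shapes incompatible")
    N, C, D, H, W = image.data.shape
    f, t, unclamped = _corner_data(df.data, (D, H, W))
    img_flat = image.data.reshape(N, C, D * H * W).astype(np.float64)

    corners = []
    out = np.zeros((N, C, D * H * W), dtype=np.float64)
    for bits in itertools.product((0, 1), repeat=3):
        idx = ((f[:, 0] + bits[0]) * (H * W)
               + (f[:, 1] + bits[1]) * W
               + (f[:, 2] + bits[2])).reshape(N, D * H * W)
        wts = np.ones((N, D, H, W), dtype=np.float64)
        for a in range(3):
            wts = wts * (t[:, a] if bits[a] else (1.0 - t[:, a]))
        wts = wts.reshape(N, D * H * W)
        vals = np.take_along_axis(img_flat, idx[:, None, :], axis=2)
        out += wts[:, None, :] * vals
        corners.append((bits, idx, wts, vals))

    def grad_image(g):
        gflat = g.reshape(N, C, D * H * W)
        dimg = np.zeros(N * C * D * H * W, dtype=np.float64)
        chan_off = (np.arange(N)[:, None, None] * C
                    + np.arange(C)[None, :, None]) * (D * H * W)
        for bits, idx, wts, _ in corners:
            flat_idx = (chan_off + idx[:, None, :]).ravel()
            contrib = (wts[:, None, :] * gflat).ravel()
            dimg += np.bincount(flat_idx, weights=contrib, minlength=dimg.size)
        return dimg.reshape(N, C, D, H, W)

    def grad_df(g):
        gflat = g.reshape(N, C, D * H * W)
        ddf = np.zeros((N, 3, D * H * W), dtype=np.float64)
        for bits, idx, wts, vals in corners:
            gv = (gflat * vals).sum(axis=1)  # (N, DHW)
            for a in range(3):
                # d(weight)/dt_a times the other two axes' weights
                other = np.ones((N, D, H, W), dtype=np.float64)
                for aa in range(3):
                    if aa != a:
                        other = other * (t[:, aa] if bits[aa] else (1.0 - t[:, aa]))
                sign = 1.0 if bits[a] else -1.0
                ddf[:, a] += sign * other.reshape(N, D * H * W) * gv
        ddf = ddf.reshape(N, 3, D, H, W)
        ddf[~unclamped] = 0.0  # clamped samples do not move with df
        return ddf

    return Tensor(out.reshape(N, C, D, H, W).astype(np.float32),
                  parents=((image, grad_image), (df, grad_df)))


def trilinear_sample(image: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Plain-numpy trilinear warp of one (D, H, W) image by a (D, H, W, 3)
    voxel-displacement field, border-clamped. No gradients."""
    image = np.asarray(image, dtype=np.float64)
    df = np.asarray(df, dtype=np.float64)
    if image.shape != df.shape[:-1] or df.shape[-1] != 3:
        raise ValueError(f"shape mismatch: image {image.shape}, df {df.shape}")
    t = Tensor(image[None, None])
    d = Tensor(np.moveaxis(df, -1, 0)[None])
    return warp_tensor(t, d).data[0, 0].astype(np.float64)


# ----------------------------------------------------------------- losses

def mse_loss(a: Tensor, b: Tensor) -> Tensor:
    """Mean over all elements of the squared difference."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"mse: shapes differ {a.data.shape} vs {b.data.shape}")
    diff = a.data.astype(np.float64) - b.data.astype(np.float64)
    n = diff.size
    out = np.array((diff ** 2).sum() / n)

    def grad_a(g):
        return g * 2.0 * diff / n

    def grad_b(g):
        return -g * 2.0 * diff / n

    return Tensor(out, parents=((a, grad_a), (b, grad_b)))


def bce_loss(prob: Tensor, target: np.ndarray, eps: float = BCE_EPS) -> Tensor:
    """Mean voxelwise binary cross-entropy with probability clipping."""
    tgt = np.asarray(target, dtype=np.float64)
    if prob.data.shape != tgt.shape:
        raise ValueError(f"bce: shapes differ {prob.data.shape} vs {tgt.shape}")
    p = np.clip(prob.data.astype(np.float64), eps, 1.0 - eps)
    inside = (prob.data > eps) & (prob.data < 1.0 - eps)
    n = p.size
    out = np.array(-(tgt * np.log(p) + (1.0 - tgt) * np.log(1.0 - p)).sum() / n)

    def grad_p(g):
        d = (p - tgt) / (p * (1.0 - p)) / n
        return g * np.where(inside, d, 0.0)

    return Tensor(out, parents=((prob, grad_p),))


def bce_with_logits_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed from pre-sigmoid logits.

    Numerically equals ``bce_loss(sigmoid(logits), target)`` but its
    gradient, (p - y)/n, survives output saturation — with a separate
    sigmoid node the p(1-p) factor underflows once the network becomes
    confident and the loss can no longer recover mislabelled voxels.
    """
    tgt = np.asarray(target, dtype=np.float64)
    if logits.data.shape != tgt.shape:
        raise ValueError(f"bce: shapes differ {logits.data.shape} vs {tgt.shape}")
    z = logits.data.astype(np.float64)
    # log(1 + exp(-|z|)) + max(z,0) - z*y, the standard stable form
    loss_vox = np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0.0) - z * tgt
    n = z.size
    out = np.array(loss_vox.sum() / n)
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def grad_logits(g):
        return g * (p - tgt) / n

    return Tensor(out, parents=((logits, grad_logits),))


def smoothness_loss(df: Tensor) -> Tensor:
    """Sum over voxels of the squared spatial gradient of the displacement
    field, forward finite differences (zero at the far face), averaged over
    the batch axis.

    df: (N, 3, D, H, W).
    """
    d = df.data.astype(np.float64)
    N = d.shape[0]
    diffs = []
    total = 0.0
    for axis in range(2, 5):
        dd = np.diff(d, axis=axis)
        diffs.append(dd)
        total += (dd ** 2).sum()
    out = np.array(total / N)

    def grad_df(g):
        gd = np.zeros_like(d)
        for axis, dd in zip(range(2, 5), diffs):
            sl_hi = [slice(None)] * 5
            sl_lo = [slice(None)] * 5
            sl_hi[axis] = slice(1, None)
            sl_lo[axis] = slice(None, -1)
            gd[tuple(sl_hi)] += 2.0 * dd
            gd[tuple(sl_lo)] -= 2.0 * dd
        return g * gd / N

    return Tensor(out, parents=((df, grad_df),))


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    return Tensor(out, parents=((a, lambda g: g), (b, lambda g: g)))


def scale(a: Tensor, s: float) -> Tensor:
    return Tensor(a.data * s, parents=((a, lambda g: g * s),))


# -------------------------------------------------------------- optimizer

class Adam:
    """Adam with bias correction; state per parameter tensor."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]
        self.v = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = (p.data.astype(np.float64)
                      - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
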