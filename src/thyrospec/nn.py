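"""Minimal feed-forward network layers with explicit backpropagation.

Convolutions are stride-1, zero-padded to preserve shape, and are evaluated
as im2col matrix products (float32 GEMM), which keeps CPU training of the
small block classifiers in this package fast.  Every layer implements
``forward(x, train=...)`` and ``backward(dy)``; parameters and their
gradients live in ``params`` / ``grads`` dicts keyed by name.

Two layers intentionally use straight-through gradients: the per-sample PCA
bridge treats its projection (mean and loading rows) as a constant linear map
during backpropagation, and the per-channel standardizer treats its mean and
standard deviation as constants.  Differentiating through eigenvectors is
numerically fragile and neither statistic carries trainable parameters.
"""

from __future__ import annotations

import numpy as np

from thyrospec.errors import ShapeError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Layer:
    """Base layer; stateless layers only override forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# im2col helpers (stride 1, same padding, odd kernels)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, ksize: tuple[int, ...]) -> np.ndarray:
    """(N, C, *spatial) -> (N, L, C*prod(ksize)) with zero same-padding."""
    nd = len(ksize)
    pads = [(0, 0), (0, 0)] + [(k // 2, k // 2) for k in ksize]
    xp = np.pad(x, pads)
    win = np.lib.stride_tricks.sliding_window_view(
        xp, ksize, axis=tuple(range(2, 2 + nd)))
    # win: (N, C, *spatial, *ksize) -> (N, *spatial, C, *ksize)
    n, c = x.shape[:2]
    spatial = x.shape[2:]
    perm = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    cols = win.transpose(perm).reshape(n, int(np.prod(spatial)),
                                       c * int(np.prod(ksize)))
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, xshape: tuple[int, ...],
            ksize: tuple[int, ...]) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    nd = len(ksize)
    n, c = xshape[:2]
    spatial = xshape[2:]
    pads = [k // 2 for k in ksize]
    padded_shape = (n, c) + tuple(s + 2 * p for s, p in zip(spatial, pads))
    dxp = np.zeros(padded_shape, dtype=dcols.dtype)
    d = dcols.reshape((n,) + spatial + (c,) + ksize)
    # move channel axis next to batch: (N, C, *spatial, *ksize)
    perm = (0, 1 + nd) + tuple(range(1, 1 + nd)) + tuple(range(2 + nd, 2 + 2 * nd))
    d = d.transpose(perm)
    for offs in np.ndindex(*ksize):
        sl = (slice(None), slice(None)) + tuple(
            slice(o, o + s) for o, s in zip(offs, spatial))
        dxp[sl] += d[(slice(None), slice(None)) + (slice(None),) * nd
                     + tuple(offs)]
    crop = (slice(None), slice(None)) + tuple(
        slice(p, p + s) for p, s in zip(pads, spatial))
    return dxp[crop]


class _ConvND(Layer):
    """Shared stride-1 same-padding convolution over 1/2/3 spatial dims."""

    def __init__(self, in_ch: int, out_ch: int, ksize: tuple[int, ...],
                 rng: np.random.Generator) -> None:
        super().__init__()
        if any(k % 2 == 0 for k in ksize):
            raise ValueError("kernel extents must be odd for same padding")
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, tuple(ksize)
        fan_in = in_ch * int(np.prod(ksize))
        self.params["w"] = _he_init(rng, (out_ch, fan_in), fan_in)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self._cache = None

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.shape[1] != self.in_ch:
            raise ShapeError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        if any(s < 1 for s in x.shape[2:]):
            raise ShapeError(f"empty spatial extent in input {x.shape}")
        # same padding keeps extents smaller than the kernel well-defined
        cols = _im2col(x, self.ksize)                      # (N, L, F)
        y = cols @ self.params["w"].T + self.params["b"]   # (N, L, O)
        spatial = x.shape[2:]
        y = np.moveaxis(y.reshape((x.shape[0],) + spatial + (self.out_ch,)),
                        -1, 1)
        self._cache = (cols, x.shape) if train else None
        return np.ascontiguousarray(y)

    def backward(self, dy):
        cols, xshape = self._cache
        n = dy.shape[0]
        dyf = np.moveaxis(dy, 1, -1).reshape(n, -1, self.out_ch)  # (N, L, O)
        self.grads["w"] = np.einsum("nlo,nlf->of", dyf, cols, optimize=True)
        self.grads["b"] = dyf.sum(axis=(0, 1))
        dcols = dyf @ self.params["w"]                      # (N, L, F)
        return _col2im(dcols, xshape, self.ksize)


class Conv3D(_ConvND):
    """3-D convolution over (h, w, spectral), input (N, C, h, w, s)."""

    def __init__(self, in_ch, out_ch, ksize=(3, 3, 3), rng=None):
        super().__init__(in_ch, out_ch, tuple(ksize), rng)


class Conv2D(_ConvND):
    """2-D convolution, input (N, C, H, W)."""

    def __init__(self, in_ch, out_ch, ksize=(3, 3), rng=None):
        super().__init__(in_ch, out_ch, tuple(ksize), rng)


class Conv1D(_ConvND):
    """1-D convolution along the spectral axis, input (N, C, B)."""

    def __init__(self, in_ch, out_ch, ksize=(3,), rng=None):
        super().__init__(in_ch, out_ch, tuple(ksize), rng)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class MaxPool2D(Layer):
    """2x2 max pooling (floor semantics); dimensions of size 1 pass through."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        s = self.size
        ph, pw = (h // s, w // s) if h >= s and w >= s else (0, 0)
        if ph == 0 or pw == 0:  # too small to pool
            self._passthrough = True
            return x
        self._passthrough = False
        xc = x[:, :, :ph * s, :pw * s]
        self._xshape = x.shape
        blocks = xc.reshape(n, c, ph, s, pw, s)
        y = blocks.max(axis=(3, 5))
        self._blocks = blocks
        self._y = y
        return y

    def backward(self, dy):
        if self._passthrough:
            return dy
        n, c, h, w = self._xshape
        s = self.size
        ph, pw = dy.shape[2], dy.shape[3]
        mask = self._blocks == self._y[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        d = mask * (dy[:, :, :, None, :, None] / counts)
        dx = np.zeros((n, c, h, w), dtype=dy.dtype)
        dx[:, :, :ph * s, :pw * s] = d.reshape(n, c, ph * s, pw * s)
        return dx


class Recombine3DTo2D(Layer):
    """Stack 3-D conv channels and spectral planes into 2-D channels.

    (N, C, h, w, s) -> (N, C*s, h, w); with the defaults of 32 kernels on a
    3-plane spectral axis this realizes the 32 x (h, w, 3) -> (h, w, 96)
    recombination.
    """

    def forward(self, x, train=False):
        n, c, h, w, s = x.shape
        self._shape = x.shape
        return np.ascontiguousarray(
            x.transpose(0, 1, 4, 2, 3).reshape(n, c * s, h, w))

    def backward(self, dy):
        n, c, h, w, s = self._shape
        return np.ascontiguousarray(
            dy.reshape(n, c, s, h, w).transpose(0, 1, 3, 4, 2))


class PCABridge(Layer):
    """Per-sample PCA over pixels: (N, C, H, W) -> (N, k, H, W).

    For each sample the H*W pixels form an (H*W, C) matrix whose top-k
    covariance eigenvectors (variance-sorted, deterministic sign: the
    largest-magnitude coefficient of each component is positive) define the
    projection.  The projection is treated as a constant linear map during
    backpropagation.  With ``projection`` given, a frozen global projection
    (mean, components) is applied instead.
    """

    def __init__(self, k: int = 3, projection: tuple[np.ndarray, np.ndarray] | None = None):
        super().__init__()
        self.k = k
        self.projection = projection

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h * w < self.k:
            raise ShapeError(f"need >= {self.k} pixels, got {h * w}")
        pix = x.transpose(0, 2, 3, 1).reshape(n, h * w, c).astype(np.float64)
        if self.projection is not None:
            mean, comps = self.projection
            comps_b = np.broadcast_to(comps, (n,) + comps.shape)
            centred = pix - mean
        else:
            mean = pix.mean(axis=1, keepdims=True)
            centred = pix - mean
            cov = centred.transpose(0, 2, 1) @ centred / max(h * w - 1, 1)
            evals, evecs = np.linalg.eigh(cov)          # ascending
            comps_b = evecs[:, :, ::-1][:, :, :self.k].transpose(0, 2, 1)
            # deterministic sign: largest-|coeff| entry positive
            jmax = np.argmax(np.abs(comps_b), axis=2)
            signs = np.sign(np.take_along_axis(comps_b, jmax[:, :, None],
                                               axis=2))
            signs[signs == 0] = 1.0
            comps_b = comps_b * signs
        y = centred @ comps_b.transpose(0, 2, 1)        # (N, HW, k)
        self._comps = comps_b
        self._hw = (h, w)
        return np.ascontiguousarray(
            y.reshape(n, h, w, self.k).transpose(0, 3, 1, 2).astype(np.float32))

    def backward(self, dy):
        n, k, h, w = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(n, h * w, k).astype(np.float64)
        dx = dyf @ self._comps                          # (N, HW, C)
        c = dx.shape[2]
        return np.ascontiguousarray(
            dx.reshape(n, h, w, c).transpose(0, 3, 1, 2).astype(np.float32))


class ChannelStandardize(Layer):
    """Per-sample, per-channel standardization over the spatial extent."""

    def __init__(self, eps: float = 1e-6) -> None:
        super().__init__()
        self.eps = eps

    def forward(self, x, train=False):
        axes = tuple(range(2, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        sd = x.std(axis=axes, keepdims=True)
        self._scale = 1.0 / (sd + self.eps)
        return (x - mu) * self._scale

    def backward(self, dy):
        # straight-through: mu and sd treated as constants
        return dy * self._scale


class AdaptiveAvgPool2D(Layer):
    """Average-pool (N, C, H, W) to a fixed (oh, ow) output grid."""

    def __init__(self, output_size: tuple[int, int] = (1, 1)) -> None:
        super().__init__()
        self.oh, self.ow = output_size

    @staticmethod
    def _bounds(n: int, o: int) -> list[tuple[int, int]]:
        edges = np.linspace(0, n, o + 1).round().astype(int)
        return [(edges[i], max(edges[i + 1], edges[i] + 1)) for i in range(o)]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        self._xshape = x.shape
        rb = self._bounds(h, self.oh)
        cb = self._bounds(w, self.ow)
        self._bins = (rb, cb)
        y = np.empty((n, c, self.oh, self.ow), dtype=x.dtype)
        for i, (r0, r1) in enumerate(rb):
            for j, (c0, c1) in enumerate(cb):
                y[:, :, i, j] = x[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
        return y

    def backward(self, dy):
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        rb, cb = self._bins
        for i, (r0, r1) in enumerate(rb):
            for j, (c0, c1) in enumerate(cb):
                area = (r1 - r0) * (c1 - c0)
                dx[:, :, r0:r1, c0:c1] += dy[:, :, i, j, None, None] / area
        return dx


class GlobalAvgPoolND(Layer):
    """Mean over all spatial axes: (N, C, ...) -> (N, C)."""

    def forward(self, x, train=False):
        self._xshape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dy):
        spatial = self._xshape[2:]
        area = int(np.prod(spatial))
        expand = dy.reshape(dy.shape + (1,) * len(spatial))
        return np.broadcast_to(expand / area, self._xshape).copy()


class Flatten(Layer):
    def forward(self, x, train=False):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.params["w"] = _he_init(rng, (out_dim, in_dim), in_dim)
        self.params["b"] = np.zeros(out_dim, dtype=np.float32)

    def forward(self, x, train=False):
        x = x.astype(np.float32)
        self._x = x if train else None
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dy):
        self.grads["w"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["w"]


class Network:
    """A plain sequential container."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        for layer in self.layers:
            for name, p in layer.params.items():
                yield layer, name, p

    def n_params(self) -> int:
        return sum(p.size for _, _, p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": p for i, layer in enumerate(self.layers)
                for name, p in layer.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(state[f"{i}.{name}"],
                                                dtype=np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           class_w: np.ndarray) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy; returns (loss, dlogits).

    The loss is the weight-normalized average of per-sample negative
    log-likelihoods; with equal weights it reduces to the ordinary mean.
    """
    p = softmax(logits.astype(np.float64))
    n = len(labels)
    w = np.asarray(class_w, dtype=np.float64)[labels]
    wsum = w.sum()
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    loss = float((w * nll).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, grad.astype(np.float32)


class SGD:
    """Stochastic gradient descent with optional momentum and norm clipping."""

    def __init__(self, net: Network, lr: float = 0.001, momentum: float = 0.0,
                 clip_norm: float | None = None):
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self._vel: dict[int, np.ndarray] = {}

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(sum(
                float(np.sum(layer.grads[name].astype(np.float64) ** 2))
                for layer, name, _ in self.net.parameters()))
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for i, (layer, name, p) in enumerate(self.net.parameters()):
            g = layer.grads[name].astype(np.float32) * scale
            if self.momentum:
                v = self._vel.get(i)
                v = g if v is None else self.momentum * v + g
                self._vel[i] = v
                g = v
            p -= self.lr * g
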