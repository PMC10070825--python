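"""Trainable layers with explicit forward/backward passes.

Each layer caches what its backward pass needs during ``forward`` and
exposes its parameters as :class:`Param` objects that an optimizer updates
in place.  Shapes follow the (N, C, H, W) convention throughout.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .batchnorm import BatchNormParams, batch_normalize

__all__ = ["Param", "Conv3x3", "Conv1x1", "BatchNorm2d", "ReLU",
           "MaxPool2", "TransposeUp2", "BilinearUp2"]


class Param:
    """A named trainable array and its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv3x3:
    """Same-padded stride-1 3x3 convolution, He-uniform initialized."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "conv"):
        self.w = Param(f"{name}.w", he_uniform(rng, (cout, cin, 3, 3), fan_in=cin * 9))
        self.b = Param(f"{name}.b", np.zeros(cout))
        self._cols = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y, cols = F.conv3x3_forward(x, self.w.data, self.b.data)
        self._cols = cols if training else None
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx, dw, db = F.conv3x3_backward(dout, self._cols, self.w.data)
        self.w.grad += dw
        self.b.grad += db
        self._cols = None
        return dx

    def params(self):
        return [self.w, self.b]


class Conv1x1:
    """Per-pixel linear map across channels (the classification head)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "head"):
        self.w = Param(f"{name}.w", he_uniform(rng, (cout, cin), fan_in=cin))
        self.b = Param(f"{name}.b", np.zeros(cout))
        self._xflat = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y, xflat = F.conv1x1_forward(x, self.w.data, self.b.data)
        self._xflat = xflat if training else None
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx, dw, db = F.conv1x1_backward(dout, self._xflat, self.w.data)
        self.w.grad += dw
        self.b.grad += db
        self._xflat = None
        return dx

    def params(self):
        return [self.w, self.b]


class BatchNorm2d:
    """Per-channel batch normalization over the (N, H, W) axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.bn = BatchNormParams.init(channels, eps=eps, momentum=momentum)
        self.gamma = Param(f"{name}.gamma", self.bn.gamma)
        self.beta = Param(f"{name}.beta", self.bn.beta)
        # the Param arrays become the live gamma/beta so optimizer updates
        # are visible to batch_normalize
        self.bn.gamma = self.gamma.data
        self.bn.beta = self.beta.data
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = batch_normalize(x, self.bn, mode="train" if training else "eval")
        if training:
            n, c, h, w = x.shape
            flat = x.transpose(0, 2, 3, 1).reshape(-1, c)
            mu = flat.mean(axis=0)
            invstd = 1.0 / np.sqrt(flat.var(axis=0) + self.bn.eps)
            xhat = (flat - mu) * invstd
            self._cache = (xhat, invstd.astype(np.float32), x.shape)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd, shape = self._cache
        n, c, h, w = shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, c)
        self.gamma.grad += (dflat * xhat).sum(axis=0)
        self.beta.grad += dflat.sum(axis=0)
        # dx for the batch-statistics path: remove the per-channel mean of dy
        # and the component along xhat before rescaling
        dmean = dflat.mean(axis=0)
        dproj = (dflat * xhat).mean(axis=0)
        dx = (self.gamma.data * invstd) * (dflat - dmean - xhat * dproj)
        self._cache = None
        return np.ascontiguousarray(
            dx.reshape(n, h, w, c).transpose(0, 3, 1, 2))

    def params(self):
        return [self.gamma, self.beta]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        self._mask = x > 0 if training else None
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling with stride 2; ties route to the first element."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, (n, c, h, w))
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return np.ascontiguousarray(dx).reshape(n, c, h, w)

    def params(self):
        return []


class TransposeUp2:
    """Transposed 2x2 stride-2 convolution (learned 2x upsampling).

    Kernel and stride coincide, so each input pixel paints a disjoint 2x2
    output block: the whole map is one matmul and its backward is exact.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "up"):
        self.w = Param(f"{name}.w", he_uniform(rng, (cin, cout, 2, 2), fan_in=cin))
        self.b = Param(f"{name}.b", np.zeros(cout))
        self._xflat = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, cin, h, w = x.shape
        cout = self.w.data.shape[1]
        xflat = np.ascontiguousarray(x.transpose(0, 2, 3, 1).reshape(-1, cin))
        y = xflat @ self.w.data.reshape(cin, cout * 4)
        y = y.reshape(n, h, w, cout, 2, 2).transpose(0, 3, 1, 4, 2, 5)
        y = np.ascontiguousarray(y).reshape(n, cout, 2 * h, 2 * w)
        y += self.b.data[None, :, None, None]
        self._xflat = xflat if training else None
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, cout, h2, w2 = dout.shape
        cin = self.w.data.shape[0]
        h, w = h2 // 2, w2 // 2
        d = dout.reshape(n, cout, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        dflat = np.ascontiguousarray(d).reshape(-1, cout * 4)
        self.w.grad += (self._xflat.T @ dflat).reshape(self.w.data.shape)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dx = dflat @ self.w.data.reshape(cin, cout * 4).T
        self._xflat = None
        return np.ascontiguousarray(dx.reshape(n, h, w, cin).transpose(0, 3, 1, 2))

    def params(self):
        return [self.w, self.b]


def _bilinear_matrix(n_out: int) -> np.ndarray:
    """1D factor-2 bilinear interpolation matrix (half-pixel centers)."""
    n_in = n_out // 2
    u = np.zeros((n_out, n_in), dtype=np.float32)
    for i in range(n_out):
        src = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        for k, wgt in ((lo, 1 - frac), (lo + 1, frac)):
            k = min(max(k, 0), n_in - 1)  # clamp at the borders
            u[i, k] += wgt
    return u


class BilinearUp2:
    """Fixed bilinear 2x upsampling followed by a learned 1x1 channel map.

    Alternative to :class:`TransposeUp2`; the interpolation itself carries
    no parameters, so its backward pass is the transpose of the
    interpolation matrices.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "up"):
        self.proj = Conv1x1(cin, cout, rng, name=f"{name}.proj")
        self._u = {}

    def _mats(self, h: int, w: int):
        key = (h, w)
        if key not in self._u:
            self._u[key] = (_bilinear_matrix(2 * h), _bilinear_matrix(2 * w))
        return self._u[key]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        ur, uc = self._mats(h, w)
        y = np.einsum("ih,nchw->nciw", ur, x, optimize=True)
        y = np.einsum("jw,nciw->ncij", uc, y, optimize=True)
        self._shape = (h, w)
        return self.proj.forward(np.ascontiguousarray(y), training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.proj.backward(dout)
        h, w = self._shape
        ur, uc = self._mats(h, w)
        d = np.einsum("jw,ncij->nciw", uc, d, optimize=True)
        d = np.einsum("ih,nciw->nchw", ur, d, optimize=True)
        return np.ascontiguousarray(d)

    def params(self):
        return self.proj.params()
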