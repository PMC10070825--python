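"""Low-level array ops for the segmentation network.

Convolutions are evaluated as im2col + one BLAS matmul; backward passes are
hand-derived adjoints of the forward maps.  Everything runs in float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "im2col3x3",
    "conv3x3_forward",
    "conv3x3_backward",
    "conv1x1_forward",
    "conv1x1_backward",
    "softmax",
]


def im2col3x3(x: np.ndarray) -> np.ndarray:
    """Unfold 3x3 neighborhoods (zero-padded) of ``x`` (N,C,H,W) into rows.

    Returns a contiguous (N*H*W, C*9) matrix; row order is (n, i, j).
    """
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    v = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
    return np.ascontiguousarray(cols, dtype=x.dtype)


def conv3x3_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """Same-padded stride-1 3x3 convolution.

    x: (N,Cin,H,W); weight: (Cout,Cin,3,3); bias: (Cout,).
    Returns (y, cols) with y (N,Cout,H,W); cols is cached for backward.
    """
    n, cin, h, w = x.shape
    cout = weight.shape[0]
    cols = im2col3x3(x)
    wmat = weight.reshape(cout, cin * 9)
    y = cols @ wmat.T
    y += bias
    return y.reshape(n, h, w, cout).transpose(0, 3, 1, 2), cols


def conv3x3_backward(dout: np.ndarray, cols: np.ndarray, weight: np.ndarray):
    """Gradients of conv3x3_forward w.r.t. input, weight and bias.

    dx is itself a same-padded correlation of dout with the spatially
    flipped, channel-transposed kernel (the exact adjoint under zero
    padding), so it reuses the same im2col machinery.
    """
    n, cout, h, w = dout.shape
    cin = weight.shape[1]
    dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1).reshape(n * h * w, cout))
    dw = (dflat.T @ cols).reshape(weight.shape)
    db = dflat.sum(axis=0)
    wflip = np.ascontiguousarray(weight.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    dcols = im2col3x3(dout)
    dx = dcols @ wflip.reshape(cin, cout * 9).T
    dx = dx.reshape(n, h, w, cin).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(dx), dw, db


def conv1x1_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """1x1 convolution: per-pixel linear map across channels.

    weight: (Cout, Cin).  Returns (y, xflat) with xflat cached for backward.
    """
    n, cin, h, w = x.shape
    xflat = np.ascontiguousarray(x.transpose(0, 2, 3, 1).reshape(-1, cin))
    y = xflat @ weight.T + bias
    return y.reshape(n, h, w, -1).transpose(0, 3, 1, 2), xflat


def conv1x1_backward(dout: np.ndarray, xflat: np.ndarray, weight: np.ndarray):
    n, cout, h, w = dout.shape
    dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1).reshape(-1, cout))
    dw = dflat.T @ xflat
    db = dflat.sum(axis=0)
    dx = (dflat @ weight).reshape(n, h, w, -1).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(dx), dw, db


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
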