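"""Batch normalization, written out explicitly.

Training mode standardizes each channel by the batch mean and the *biased*
batch variance (divisor m, the number of activations pooled per channel),

    mu_B    = (1/m) sum_i x_i
    sigma^2 = (1/m) sum_i (x_i - mu_B)^2
    xhat_i  = (x_i - mu_B) / sqrt(sigma^2 + eps)
    y_i     = gamma * xhat_i + beta

and keeps exponential running averages of (mu_B, sigma^2) that replace the
batch statistics at inference time.  The eps stabilizer is *added* under the
root: it exists precisely to keep the denominator positive when a channel's
batch variance vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BatchNormParams", "batch_normalize"]


@dataclass
class BatchNormParams:
    """Learnable scale/shift plus running statistics for one BN layer.

    gamma/beta are the learnable per-channel affine parameters; ``m`` records
    how many activations per channel the last training-mode call pooled.
    """

    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-5
    momentum: float = 0.1
    running_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    running_var: np.ndarray = field(default=None)  # type: ignore[assignment]
    m: int = 0

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=np.float32)
        self.beta = np.asarray(self.beta, dtype=np.float32)
        if self.gamma.shape != self.beta.shape:
            raise ValueError("gamma and beta must have the same shape")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        c = self.gamma.shape[0]
        if self.running_mean is None:
            self.running_mean = np.zeros(c, dtype=np.float32)
        if self.running_var is None:
            self.running_var = np.ones(c, dtype=np.float32)
        self.running_mean = np.asarray(self.running_mean, dtype=np.float32)
        self.running_var = np.asarray(self.running_var, dtype=np.float32)
        if np.any(self.running_var < 0):
            raise ValueError("running_var must be nonnegative")

    @classmethod
    def init(cls, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> "BatchNormParams":
        """Fresh parameters: gamma=1, beta=0, zero mean / unit variance stats."""
        return cls(gamma=np.ones(channels, dtype=np.float32),
                   beta=np.zeros(channels, dtype=np.float32),
                   eps=eps, momentum=momentum)

    @property
    def n_channels(self) -> int:
        return self.gamma.shape[0]


def _channel_view(batch: np.ndarray):
    """Reshape (N,C) or (N,C,H,W) input to (M, C) with M pooled activations."""
    x = np.asarray(batch)
    if x.ndim == 2:
        return x, x.shape
    if x.ndim == 4:
        n, c, h, w = x.shape
        return x.transpose(0, 2, 3, 1).reshape(-1, c), x.shape
    raise ValueError(f"expected (N,C) or (N,C,H,W) batch, got shape {x.shape}")


def batch_normalize(batch: np.ndarray, params: BatchNormParams, mode: str = "train") -> np.ndarray:
    """Apply batch normalization to a per-channel activation collection.

    ``batch`` is (N, C) or (N, C, H, W); channels live on axis 1.  In train
    mode the batch statistics are used and the running averages updated in
    place; in eval mode the running averages are used instead.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    flat, shape = _channel_view(batch)
    if flat.shape[0] == 0:
        raise ValueError("batch is empty")
    if flat.shape[1] != params.n_channels:
        raise ValueError(
            f"batch has {flat.shape[1]} channels but params expect {params.n_channels}")
    if mode == "train":
        m = flat.shape[0]
        if m < 2:
            raise ValueError("train-mode batch normalization needs >= 2 elements per channel")
        mu = flat.mean(axis=0)
        var = flat.var(axis=0)  # biased, divisor m
        params.running_mean = ((1 - params.momentum) * params.running_mean
                               + params.momentum * mu).astype(np.float32)
        params.running_var = ((1 - params.momentum) * params.running_var
                              + params.momentum * var).astype(np.float32)
        params.m = m
    else:
        mu = params.running_mean
        var = params.running_var
    xhat = (flat - mu) / np.sqrt(var + params.eps)
    y = params.gamma * xhat + params.beta
    if len(shape) == 4:
        n, c, h, w = shape
        y = y.reshape(n, h, w, c).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(y, dtype=np.result_type(batch, np.float32))
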