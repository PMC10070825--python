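"""Encoder-decoder segmentation network (U-Net).

Each encoder stage applies two same-padded 3x3 convolutions, each followed
by batch normalization and ReLU, then halves the grid with 2x2 max pooling
while doubling the feature channels (starting from ``base_channels``).  The
decoder mirrors this: a learned 2x upsampling halves the channels, the
result is concatenated with the matching encoder output, and two more
conv-BN-ReLU pairs follow.  A final 1x1 convolution maps to the four class
logits; softmax turns them into per-pixel probabilities over
{background, RV, myocardium, LV}.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict

import numpy as np

from .functional import softmax
from .layers import (BatchNorm2d, BilinearUp2, Conv1x1, Conv3x3, MaxPool2,
                     ReLU, TransposeUp2)

__all__ = ["NetworkConfig", "UNet", "build_network", "forward", "predict_mask",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    depth: number of downsampling stages; input_size must be divisible by
    2**depth.  base_channels: feature channels of the first stage; stage k
    of the encoder has base_channels * 2**k.  up_mode selects the decoder
    upsampling: "transpose" (learned 2x2 stride-2 transposed convolution)
    or "bilinear" (fixed interpolation + 1x1 projection).
    """

    depth: int = 4
    base_channels: int = 64
    n_classes: int = 4
    input_size: int = 64
    up_mode: str = "transpose"
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {2 ** self.depth}")
        if self.up_mode not in ("transpose", "bilinear"):
            raise ValueError(f"unknown up_mode {self.up_mode!r}")

    @property
    def encoder_channels(self) -> list[int]:
        return [self.base_channels * 2 ** k for k in range(self.depth)]


class _DoubleConv:
    """(conv3x3 -> BN -> ReLU) x 2."""

    def __init__(self, cin, cout, rng, cfg: NetworkConfig, name):
        self.ops = []
        for i, ci in enumerate((cin, cout)):
            self.ops.append(Conv3x3(ci, cout, rng, name=f"{name}.conv{i}"))
            self.ops.append(BatchNorm2d(cout, eps=cfg.bn_eps,
                                        momentum=cfg.bn_momentum, name=f"{name}.bn{i}"))
            self.ops.append(ReLU())

    def forward(self, x, training):
        for op in self.ops:
            x = op.forward(x, training)
        return x

    def backward(self, d):
        for op in reversed(self.ops):
            d = op.backward(d)
        return d

    def params(self):
        return [p for op in self.ops for p in op.params()]


class UNet:
    """The assembled network; see the module docstring for the topology."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.encoder_channels
        up_cls = TransposeUp2 if config.up_mode == "transpose" else BilinearUp2

        self.enc = []
        cin = 1
        for k, c in enumerate(ch):
            self.enc.append(_DoubleConv(cin, c, rng, config, f"enc{k}"))
            cin = c
        self.pools = [MaxPool2() for _ in ch]
        bottleneck_ch = config.base_channels * 2 ** config.depth
        self.bottleneck = _DoubleConv(ch[-1], bottleneck_ch, rng, config, "bottleneck")

        self.ups, self.dec = [], []
        cprev = bottleneck_ch
        for k in reversed(range(config.depth)):
            self.ups.append(up_cls(cprev, ch[k], rng, name=f"up{k}"))
            self.dec.append(_DoubleConv(2 * ch[k], ch[k], rng, config, f"dec{k}"))
            cprev = ch[k]
        self.head = Conv1x1(ch[0], config.n_classes, rng, name="head")
        self._skip_ch = None

    # -- plumbing ---------------------------------------------------------

    def _blocks(self):
        yield from self.enc
        yield from self.pools
        yield self.bottleneck
        yield from self.ups
        yield from self.dec
        yield self.head

    def params(self):
        return [p for b in self._blocks() for p in b.params()]

    def bn_layers(self):
        for b in self._blocks():
            if isinstance(b, _DoubleConv):
                yield from (op for op in b.ops if isinstance(op, BatchNorm2d))

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    # -- forward / backward ----------------------------------------------

    def _check_input(self, x: np.ndarray):
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N,1,H,W) input, got shape {x.shape}")
        s = self.config.input_size
        if x.shape[2] != s or x.shape[3] != s:
            raise ValueError(
                f"spatial size {x.shape[2]}x{x.shape[3]} does not match "
                f"configured input_size {s}; no implicit resizing is done")

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        self._skip_ch = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, training)
            self._skip_ch.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, training)
        return self.head.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        # unwind decoder stages in reverse application order, setting aside
        # the gradient flowing into each skip connection
        dskips = []
        for up, dec, c in zip(self.ups[::-1], self.dec[::-1], self._skip_ch[::-1]):
            d = dec.backward(d)
            dskip, d = d[:, :c], d[:, c:]
            dskips.append(np.ascontiguousarray(dskip))
            d = up.backward(d)
        d = self.bottleneck.backward(d)
        # dskips[-1] belongs to the deepest encoder stage, processed first here
        for enc, pool, dskip in zip(self.enc[::-1], self.pools[::-1], dskips[::-1]):
            d = pool.backward(d)
            d = enc.backward(d + dskip)

    # -- state ------------------------------------------------------------

    def state_dict(self) -> dict:
        state = {p.name: p.data.copy() for p in self.params()}
        for i, bn in enumerate(self.bn_layers()):
            state[f"__bn{i}.running_mean"] = bn.bn.running_mean.copy()
            state[f"__bn{i}.running_var"] = bn.bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for p in self.params():
            p.data[...] = state[p.name]
        for i, bn in enumerate(self.bn_layers()):
            bn.bn.running_mean = state[f"__bn{i}.running_mean"].astype(np.float32).copy()
            bn.bn.running_var = state[f"__bn{i}.running_var"].astype(np.float32).copy()


def build_network(config: NetworkConfig) -> UNet:
    """Construct and initialize a network from its configuration."""
    return UNet(config)


def forward(network: UNet, batch: np.ndarray) -> np.ndarray:
    """Eval-mode forward pass to per-pixel class probabilities.

    batch: (N, 1, H, W) or (N, H, W) intensities.  Returns (N, n_classes,
    H, W) softmax probabilities summing to 1 at every pixel.
    """
    x = np.asarray(batch, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    return softmax(network.forward_logits(x, training=False), axis=1)


def predict_mask(network: UNet, image: np.ndarray) -> np.ndarray:
    """Segment one slice: argmax decode of the class probabilities.

    Ties break toward the lowest class index.  Accepts a bare (H, W) array
    or anything with a ``pixels`` attribute.  Returns an (H, W) uint8
    label grid over {0: background, 1: RV, 2: myocardium, 3: LV}.
    """
    if hasattr(image, "pixels"):
        image = image.pixels
    probs = forward(network, np.asarray(image)[None])
    return probs[0].argmax(axis=0).astype(np.uint8)


def save_checkpoint(path, network: UNet) -> None:
    """Single-file versioned checkpoint: config JSON + all arrays (npz)."""
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION, "config": asdict(network.config)}
    arrays = {k.replace("/", "_"): v for k, v in network.state_dict().items()}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path) -> UNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('format_version')}")
        net = UNet(NetworkConfig(**meta["config"]))
        net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return net
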