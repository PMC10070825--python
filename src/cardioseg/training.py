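"""Training loop and end-to-end experiment driver.

The procedure: per-slice min-max intensity normalization to [0, 1],
on-the-fly augmentation (random crop, rotation, flips applied identically
to image and mask, labels always resampled nearest-neighbor), ADAM on the
compound cross-entropy + Dice loss with learning rate 0.001, batch size 4
and 18 epochs by default, batch normalization in train mode during updates
and eval mode during validation, and checkpoint selection by validation
Dice.  The train/test split is at subject level so no subject leaks across
the boundary.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .losses import LossWeights, combined_loss, one_hot, softmax_backward
from .nn.functional import softmax
from .nn.optim import Adam
from .nn.unet import UNet
from .types import GrayscaleSlice, LabelMask

__all__ = ["AugmentConfig", "TrainConfig", "TrainLog", "augment", "train",
           "run_experiment", "normalize_slice", "rotate_pair", "flip_pair",
           "crop_resize_pair"]


@dataclass
class AugmentConfig:
    """On-the-fly augmentation switches and ranges.

    crop keeps a random window of retained-fraction side length and
    resizes it back to the input size; rotation is uniform in
    [-angle, +angle] degrees; flips are independent coin flips per axis.
    """

    crop: bool = True
    crop_fraction: tuple[float, float] = (0.8, 1.0)
    rotation: bool = True
    rotation_degrees: float = 15.0
    flip_horizontal: bool = True
    flip_vertical: bool = True
    max_retries: int = 5


@dataclass
class TrainConfig:
    """Optimization hyperparameters (ADAM, lr 0.001, batch 4, 18 epochs)."""

    learning_rate: float = 1e-3
    batch_size: int = 4
    epochs: int = 18
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    loss: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (train-mode batch norm "
                             "needs at least 2 elements)")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class TrainLog:
    """Per-epoch record of training loss and validation Dice per structure."""

    records: list = field(default_factory=list)  # dicts per epoch
    seed: int = 0
    config_hash: str = ""
    n_steps: int = 0
    best_epoch: int = -1
    train_subjects: list = field(default_factory=list)
    val_subjects: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def normalize_slice(pixels: np.ndarray) -> np.ndarray:
    """Per-slice min-max scaling to [0, 1]; constant slices map to 0."""
    p = np.asarray(pixels, dtype=np.float32)
    lo, hi = float(p.min()), float(p.max())
    if hi - lo < 1e-12:
        return np.zeros_like(p)
    return (p - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# paired geometric transforms: the image interpolates, labels never blend

def flip_pair(image: np.ndarray, mask: np.ndarray, horizontal: bool, vertical: bool):
    if horizontal:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if vertical:
        image, mask = image[::-1, :], mask[::-1, :]
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def rotate_pair(image: np.ndarray, mask: np.ndarray, angle_deg: float):
    """Rotate about the grid center; linear for the image, nearest for labels."""
    img = ndimage.rotate(image, angle_deg, reshape=False, order=1,
                         mode="constant", cval=float(image.min()))
    msk = ndimage.rotate(mask, angle_deg, reshape=False, order=0,
                         mode="constant", cval=0)
    return img.astype(np.float32), msk.astype(mask.dtype)


def crop_resize_pair(image: np.ndarray, mask: np.ndarray, fraction: float,
                     row0: int, col0: int):
    """Keep a window of side round(fraction*size) at (row0, col0), zoom back."""
    h, w = image.shape
    ch, cw = max(2, round(fraction * h)), max(2, round(fraction * w))
    row0 = min(max(row0, 0), h - ch)
    col0 = min(max(col0, 0), w - cw)
    img = image[row0:row0 + ch, col0:col0 + cw]
    msk = mask[row0:row0 + ch, col0:col0 + cw]
    img = ndimage.zoom(img, (h / ch, w / cw), order=1)
    msk = ndimage.zoom(msk, (h / ch, w / cw), order=0)
    # zoom can be off by one pixel from rounding; crop/pad to the exact size
    img = img[:h, :w]
    msk = msk[:h, :w]
    return img.astype(np.float32), msk.astype(mask.dtype)


def augment(image, mask, rng: np.random.Generator,
            config: AugmentConfig | None = None):
    """Random crop / rotation / flip applied identically to image and mask.

    Accepts and returns (GrayscaleSlice, LabelMask) or plain arrays.  If a
    draw would erase every foreground pixel present in the input, it is
    redrawn (bounded retries), falling back to the identity.
    """
    cfg = config or AugmentConfig()
    wrap = isinstance(image, GrayscaleSlice)
    img = image.pixels if wrap else np.asarray(image, dtype=np.float32)
    msk = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    if img.shape != msk.shape:
        raise ValueError("image and mask must be aligned")
    fg_before = set(np.unique(msk)) - {0}

    out_img, out_msk = img, msk
    for _ in range(cfg.max_retries):
        ti, tm = img, msk
        if cfg.flip_horizontal or cfg.flip_vertical:
            ti, tm = flip_pair(
                ti, tm,
                horizontal=cfg.flip_horizontal and bool(rng.integers(2)),
                vertical=cfg.flip_vertical and bool(rng.integers(2)))
        if cfg.rotation and cfg.rotation_degrees > 0:
            ti, tm = rotate_pair(ti, tm, float(
                rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees)))
        if cfg.crop:
            frac = float(rng.uniform(*cfg.crop_fraction))
            ch = max(2, round(frac * img.shape[0]))
            cw = max(2, round(frac * img.shape[1]))
            r0 = int(rng.integers(0, img.shape[0] - ch + 1))
            c0 = int(rng.integers(0, img.shape[1] - cw + 1))
            ti, tm = crop_resize_pair(ti, tm, frac, r0, c0)
        if not fg_before or (set(np.unique(tm)) - {0}):
            out_img, out_msk = ti, tm
            break
    if wrap:
        out_img = GrayscaleSlice(out_img, spacing=image.spacing,
                                 phase_index=image.phase_index,
                                 subject_id=image.subject_id)
        out_msk = LabelMask(out_msk)
    return out_img, out_msk


# ---------------------------------------------------------------------------

def _foreground_dice(pred_labels: np.ndarray, gt_labels: np.ndarray):
    """Per-structure hard Dice over a stack of slices (validation score)."""
    out = {}
    for name, c in (("RV", 1), ("myo", 2), ("LV", 3)):
        a, b = gt_labels == c, pred_labels == c
        denom = int(a.sum()) + int(b.sum())
        out[name] = 1.0 if denom == 0 else 2.0 * int((a & b).sum()) / denom
    return out


def _prep(dataset):
    imgs = np.stack([normalize_slice(sl.pixels) for sl, _ in dataset])
    masks = np.stack([m.labels for _, m in dataset])
    subjects = [sl.subject_id for sl, _ in dataset]
    return imgs, masks, subjects


def train(network: UNet, train_set, val_set, config: TrainConfig | None = None):
    """Optimize the network on (slice, mask) pairs; returns (network, TrainLog).

    The best-validation-Dice parameters are restored into the network at
    the end.  Raises on a non-finite loss with the offending batch index
    and loss components.
    """
    cfg = config or TrainConfig()
    if not train_set:
        raise ValueError("training set is empty")
    imgs, masks, train_subjects = _prep(train_set)
    val_imgs, val_masks, val_subjects = (_prep(val_set) if val_set
                                         else (None, None, []))
    n = len(imgs)
    if n % cfg.batch_size == 1:
        raise ValueError("last batch would hold a single element, which "
                         "train-mode batch norm cannot standardize; adjust "
                         "batch_size or the training set size")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed))
    opt = Adam(network.params(), lr=cfg.learning_rate, beta1=cfg.adam_beta1,
               beta2=cfg.adam_beta2, eps=cfg.adam_eps)
    log = TrainLog(seed=cfg.seed, config_hash=cfg.config_hash(),
                   train_subjects=sorted(set(train_subjects)),
                   val_subjects=sorted(set(val_subjects)))
    best_score, best_state = -np.inf, None
    steps_per_epoch = int(np.ceil(n / cfg.batch_size))

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            xb = np.empty((len(idx), 1, *imgs.shape[1:]), dtype=np.float32)
            yb = np.empty((len(idx), *masks.shape[1:]), dtype=np.uint8)
            for j, i in enumerate(idx):
                ai, am = augment(imgs[i], masks[i], rng, cfg.augmentation)
                xb[j, 0] = ai
                yb[j] = am
            target = one_hot(yb)
            opt.zero_grad()
            logits = network.forward_logits(xb, training=True)
            probs = softmax(logits, axis=1)
            loss, gprobs = combined_loss(probs, target, cfg.loss, return_grad=True)
            if not np.isfinite(loss):
                from .losses import cross_entropy_loss, dice_loss
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {b}: "
                    f"ce={cross_entropy_loss(probs, target, cfg.loss.ce_floor)}, "
                    f"dice={dice_loss(probs, target, cfg.loss.dice_eps, cfg.loss.dice_mode)}")
            network.backward(softmax_backward(probs, gprobs).astype(np.float32))
            opt.step()
            log.n_steps += 1
            losses.append(loss)

        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_imgs is not None:
            preds = predict_batch(network, val_imgs)
            record.update({f"val_dice_{k}": v for k, v in
                           _foreground_dice(preds, val_masks).items()})
            score = np.mean([record["val_dice_RV"], record["val_dice_myo"],
                             record["val_dice_LV"]])
        else:
            score = -record["train_loss"]
        if score > best_score:
            best_score, best_state = score, network.state_dict()
            log.best_epoch = epoch
        log.records.append(record)

    if best_state is not None:
        network.load_state_dict(best_state)
    return network, log


def predict_batch(network: UNet, images: np.ndarray,
                  batch_size: int = 8) -> np.ndarray:
    """Eval-mode argmax segmentation of a stack of normalized images."""
    outs = []
    for i in range(0, len(images), batch_size):
        x = images[i:i + batch_size][:, None].astype(np.float32)
        probs = softmax(network.forward_logits(x, training=False), axis=1)
        outs.append(probs.argmax(axis=1).astype(np.uint8))
    return np.concatenate(outs)


def predict_dataset(network: UNet, dataset):
    """Segment (slice, mask) pairs; returns list of LabelMask."""
    imgs = np.stack([normalize_slice(sl.pixels) for sl, _ in dataset])
    preds = predict_batch(network, imgs)
    return [LabelMask(p) for p in preds]


def run_experiment(phantom_seed: int = 0, n_subjects: int = 40,
                   spec_ranges=None, network_config=None,
                   train_config: TrainConfig | None = None,
                   train_fraction: float = 0.8, out_dir=None):
    """Full pipeline: generate -> split 8:2 -> train -> evaluate held-out.

    Returns (MetricReport, TrainLog, network).  When ``out_dir`` is given,
    the resolved configs, the training log (CSV), the checkpoint and the
    report (CSV + JSON) are written there.
    """
    from .metrics import evaluate
    from .nn.unet import NetworkConfig, build_network, save_checkpoint
    from .phantom import generate_dataset, split_dataset

    net_cfg = network_config or NetworkConfig(depth=3, base_channels=16,
                                              input_size=64, seed=phantom_seed)
    tr_cfg = train_config or TrainConfig(seed=phantom_seed)
    dataset = generate_dataset(n_subjects, spec_ranges, seed=phantom_seed)
    train_set, test_set = split_dataset(dataset, train_fraction, seed=phantom_seed)
    network = build_network(net_cfg)
    network, log = train(network, train_set, test_set, tr_cfg)

    preds = predict_dataset(network, test_set)
    gts = [m for _, m in test_set]
    n_phases = max(sl.phase_index for sl, _ in test_set) + 1
    phase_labels = ["ED" if sl.phase_index == 0
                    else "ES" if sl.phase_index == n_phases - 1
                    else "mid" for sl, _ in test_set]
    spacings = [sl.spacing for sl, _ in test_set]
    report = evaluate(preds, gts, phase_labels, spacings=spacings)

    if out_dir is not None:
        import pathlib
        import yaml
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump({"network": asdict(net_cfg), "training": asdict(tr_cfg),
                            "n_subjects": n_subjects, "seed": phantom_seed,
                            "train_fraction": train_fraction}, fh)
        log.to_csv(out / "train_log.csv")
        save_checkpoint(out / "checkpoint.npz", network)
        report.to_csv(out / "metric_report.csv")
        report.to_json(out / "metric_report.json")
    return report, log, network
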