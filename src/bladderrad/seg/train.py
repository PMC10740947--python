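"""Training and inference for the semi-automatic segmentation model.

Training operates on 2D transverse slices drawn from inside each lesion's
VOI (including tumor-free slices when the VOI jitter extends beyond the
lesion), pooled across lesions and shuffled per epoch.  The learning rate
follows cosine annealing between ``lr_start`` and ``lr_end`` per epoch;
the optimizer is Adam with L2 weight decay.  Everything is seeded and
reproducible bit-for-bit.

Inference (:func:`predict_lesion`) applies identical preprocessing, crops
the padded probability maps back to VOI coordinates, re-embeds them in the
full volume, thresholds at 0.5 and keeps the largest 26-connected
component of the binary mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .losses import combined_loss
from .metrics import seg_metrics
from .preprocess import (
    VOIBox, center_crop_voi, crop_from_pad, minmax_normalize, pad_to_size,
    voi_from_mask,
)
from .unet import SegNetConfig, UNet, build_unet

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lr_start: float = 1e-3
    lr_end: float = 1e-5
    batch_size: int = 20
    epochs: int = 100
    weight_decay: float = 1e-4
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    w_focal: float = 1.0
    w_dice: float = 1.0
    dice_smooth: float = 1.0
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.lr_end >= self.lr_start:
            raise ValueError("lr_end must be below lr_start")
        if self.focal_gamma < 0 or not 0 < self.focal_alpha < 1:
            raise ValueError("invalid focal parameters")
        if self.w_focal < 0 or self.w_dice < 0 or (self.w_focal == 0 and self.w_dice == 0):
            raise ValueError("loss weights must be non-negative, not both zero")


def cosine_lr(t: int, total_epochs: int, lr_start: float, lr_end: float) -> float:
    """0.5 (lr_s + lr_e) + 0.5 (lr_s - lr_e) cos(pi t / T), T = epochs - 1."""
    if total_epochs <= 1:
        return lr_start
    T = total_epochs - 1
    return 0.5 * (lr_start + lr_end) + 0.5 * (lr_start - lr_end) * np.cos(np.pi * t / T)


def slices_for_sample(sample, voi: VOIBox, n: int):
    """Preprocessed (input, target) slice pairs for one lesion's VOI."""
    voi = center_crop_voi(voi, n, sample.volume.shape)
    crop = minmax_normalize(sample.volume[voi.slices])
    tgt = sample.mask[voi.slices]
    xs, ys = [], []
    for z in range(crop.shape[0]):
        xs.append(pad_to_size(crop[z], n))
        ys.append(pad_to_size(tgt[z].astype(np.float32), n))
    return np.asarray(xs, np.float32), np.asarray(ys, np.float32)


def assign_vois(samples, margin_vox=(1, 6, 6), jitter: int = 2, seed: int = 0) -> dict:
    """Seeded simulated-annotator VOIs, one per lesion id."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x701)))
    return {s.id: voi_from_mask(s.mask, margin_vox, jitter, rng) for s in samples}


@dataclass
class TrainedSegmenter:
    model: UNet
    net_cfg: SegNetConfig
    train_cfg: TrainConfig
    loss_trace: list = field(default_factory=list)
    lr_trace: list = field(default_factory=list)

    def state(self) -> dict:
        return {
            "net_cfg": self.net_cfg.__dict__,
            "train_cfg": self.train_cfg.__dict__,
            "weights": self.model.state_dict(),
            "loss_trace": self.loss_trace,
        }


def train_segmenter(samples, vois: dict, net_cfg: SegNetConfig,
                    cfg: TrainConfig) -> TrainedSegmenter:
    """Train the U-Net on all VOI slices of the given lesions."""
    if not samples:
        raise ValueError("empty training set")
    xs, ys = [], []
    for s in samples:
        x, y = slices_for_sample(s, vois[s.id], net_cfg.input_size)
        xs.append(x); ys.append(y)
    X = np.concatenate(xs)[:, None]  # (S, 1, N, N)
    Y = np.concatenate(ys)[:, None]
    n_slices = X.shape[0]
    log.info("training on %d slices from %d lesions", n_slices, len(samples))

    model = build_unet(net_cfg, seed=cfg.seed)
    opt = model.make_optimizer(cfg.lr_start, cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x7EA1)))
    loss_trace, lr_trace = [], []
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.lr_start, cfg.lr_end)
        opt.lr = lr
        lr_trace.append(float(lr))
        order = rng.permutation(n_slices)
        epoch_losses = []
        for start in range(0, n_slices, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            prob = model.forward(X[idx], train=True)
            loss, grad, _ = combined_loss(
                prob, Y[idx], cfg.focal_gamma, cfg.focal_alpha,
                cfg.dice_smooth, cfg.w_focal, cfg.w_dice, with_grad=True)
            model.backward(grad.astype(np.float32))
            opt.step()
            epoch_losses.append(loss)
        loss_trace.append(float(np.mean(epoch_losses)))
    return TrainedSegmenter(model, net_cfg, cfg, loss_trace, lr_trace)


@dataclass
class SegPrediction:
    """Probability volume and binary mask in full-volume coordinates."""

    prob: np.ndarray
    mask: np.ndarray
    voi: VOIBox


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    if n <= 1:
        return mask
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (1 + int(np.argmax(sizes)))


def predict_lesion(seg: TrainedSegmenter, sample, voi: VOIBox,
                   batch_size: int = 20) -> SegPrediction:
    """Slice-wise inference inside the VOI; outside is background."""
    n = seg.net_cfg.input_size
    voi = center_crop_voi(voi, n, sample.volume.shape)
    crop = minmax_normalize(sample.volume[voi.slices])
    xs = np.asarray([pad_to_size(crop[z], n) for z in range(crop.shape[0])],
                    np.float32)[:, None]
    probs = []
    for start in range(0, xs.shape[0], batch_size):
        probs.append(seg.model.forward(xs[start:start + batch_size], train=False))
    pp = np.concatenate(probs)[:, 0]
    prob = np.zeros(sample.volume.shape, dtype=np.float64)
    vy, vx = crop.shape[1], crop.shape[2]
    for z in range(crop.shape[0]):
        prob[voi.zmin + z][voi.slices[1], voi.slices[2]] = crop_from_pad(pp[z], (vy, vx))
    binary = prob >= seg.train_cfg.threshold
    if binary.any():
        binary = _largest_component(binary)
    return SegPrediction(prob, binary, voi)


def evaluate_cohort(seg: TrainedSegmenter, samples, vois: dict) -> dict:
    """Per-lesion DSC/recall/precision against the reference masks."""
    rows = {}
    for s in samples:
        pred = predict_lesion(seg, s, vois[s.id])
        m = seg_metrics(pred.mask, s.mask)
        rows[s.id] = {"dsc": m.dsc, "recall": m.recall, "precision": m.precision}
    return rows
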