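"""The U-shaped encoder-decoder segmentation network.

Encoder: five double-convolution blocks (each 3x3 conv -> batch norm ->
ReLU, twice) interleaved with four 2x2 max-poolings; channel width doubles
at each depth from ``base_channels``.  Decoder: four up-sampling stages
(4x4/stride-2 transpose convolution, concatenation with the same-depth
encoder feature map, double-conv).  Head: 1x1 convolution + sigmoid, one
probability map per input slice.  A 256-square input reaches a 16-square
bottleneck (depth 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Layer, MaxPool2, ReLU,
    Sequential, Sigmoid, F,
)


@dataclass
class SegNetConfig:
    input_size: int = 256
    depth: int = 4
    base_channels: int = 64

    def __post_init__(self):
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input size {self.input_size} not divisible by 2^{self.depth}")

    @property
    def bottleneck_side(self) -> int:
        return self.input_size // (2 ** self.depth)


def _double_conv(cin, cout, rng) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, 3, rng=rng), BatchNorm2d(cout), ReLU(),
        Conv2d(cout, cout, 3, rng=rng), BatchNorm2d(cout), ReLU(),
    )


class UNet:
    """2D U-Net operating on (B, 1, N, N) float32 slices."""

    def __init__(self, cfg: SegNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        c = cfg.base_channels
        d = cfg.depth
        widths = [c * (2 ** i) for i in range(d + 1)]
        self.enc = []
        cin = 1
        for w in widths:
            self.enc.append(_double_conv(cin, w, rng))
            cin = w
        self.pools = [MaxPool2() for _ in range(d)]
        self.ups = []
        self.dec = []
        for i in range(d - 1, -1, -1):
            self.ups.append(ConvTranspose2d(widths[i + 1], widths[i], rng))
            self.dec.append(_double_conv(2 * widths[i], widths[i], rng))
        self.head = Sequential(Conv2d(widths[0], 1, k=1, pad=0, rng=rng), Sigmoid())
        self.bottleneck_shape = None

    # -- plumbing ----------------------------------------------------------
    def iter_layers(self):
        for blk in self.enc:
            yield from blk.iter_layers()
        for up, dec in zip(self.ups, self.dec):
            yield up
            yield from dec.iter_layers()
        yield from self.head.iter_layers()

    def make_optimizer(self, lr, weight_decay) -> Adam:
        return Adam(list(self.iter_layers()), lr=lr, weight_decay=weight_decay)

    # -- forward / backward ------------------------------------------------
    # public interface is channel-first (B, 1, N, N); internals run NHWC
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(np.moveaxis(x, 1, -1), dtype=F)
        skips = []
        for i, blk in enumerate(self.enc):
            x = blk.forward(x, train)
            if i < self.cfg.depth:
                skips.append(x)
                x = self.pools[i].forward(x, train)
        self.bottleneck_shape = x.shape[1:3]
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=-1)
            dec._concat_split = skip.shape[-1]
            x = dec.forward(x, train)
        out = self.head.forward(x, train)
        return np.moveaxis(out, -1, 1)

    def backward(self, dprob: np.ndarray) -> None:
        d = np.ascontiguousarray(np.moveaxis(dprob, 1, -1), dtype=F)
        d = self.head.backward(d)
        dskips = []  # dskips[i] aligns with the encoder skip at depth i
        for up, dec in zip(reversed(self.ups), reversed(self.dec)):
            d = dec.backward(d)
            split = dec._concat_split
            dskips.append(d[..., :split])
            d = up.backward(np.ascontiguousarray(d[..., split:]))
        # walk encoder backwards, adding skip gradients
        for i in range(self.cfg.depth, -1, -1):
            if i < self.cfg.depth:
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            d = self.enc[i].backward(d)

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.iter_layers()):
            for j, p in enumerate(layer.params):
                state[f"p{i}_{j}"] = p
            if isinstance(layer, BatchNorm2d):
                state[f"rm{i}"] = layer.running_mean
                state[f"rv{i}"] = layer.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.iter_layers()):
            for j, p in enumerate(layer.params):
                p[...] = state[f"p{i}_{j}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"rm{i}"]
                layer.running_var[...] = state[f"rv{i}"]


def build_unet(cfg: SegNetConfig, seed: int = 0) -> UNet:
    """Construct a seeded U-Net per the architecture above."""
    return UNet(cfg, np.random.default_rng(seed))
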