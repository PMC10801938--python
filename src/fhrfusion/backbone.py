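"""SE-TCN signal backbone: multi-scale front end plus residual dilated blocks.

The backbone maps a batch of 30-minute FHR windows (B x 7200 x 1) to a
latent sequence (B x 400 x 256 with default widths) through

* MDSC — four parallel depthwise-separable convolutions with kernel sizes
  1/3/5/7, 16 channels each, concatenated to 64 channels at full length;
* five residual blocks, each with two dilated causal convolutions
  (dilations 2, 4, 8, 16, 32, kernel 15) plus batch norm, ReLU and dropout
  on the main path, and a strided 1x1 convolution followed by a
  squeeze-and-excitation channel gate on the shortcut.

Strides (3, 1, 3, 1, 2) shrink the sequence 7200 -> 2400 -> 2400 -> 800 ->
800 -> 400 (ceil division).  All convolutions read only current and past
samples; the SE gate pools over the whole window and is the one
deliberately global (non-causal) component, and can be disabled via
``se_enabled`` when strict causality is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .nn import (
    BatchNorm1d,
    CausalConv1d,
    DepthwiseSeparableConv1d,
    Dropout,
    Module,
    SEBlock,
    Tensor,
    concat,
)

__all__ = [
    "BackboneConfig",
    "MDSC",
    "SETCNBlock",
    "SETCNBackbone",
    "receptive_field",
]


@dataclass
class BackboneConfig:
    """Hyperparameters of the signal backbone.

    Defaults follow the reference architecture: kernel 15, dilations 2^L for
    L = 1..5, strides (3, 1, 3, 1, 2), channel widths (64, 64, 128, 128,
    256), MDSC kernel sizes (1, 3, 5, 7) with 16 channels per branch.
    """

    kernel_size: int = 15
    dilations: Tuple[int, ...] = (2, 4, 8, 16, 32)
    strides: Tuple[int, ...] = (3, 1, 3, 1, 2)
    channels: Tuple[int, ...] = (64, 64, 128, 128, 256)
    mdsc_kernel_sizes: Tuple[int, ...] = (1, 3, 5, 7)
    mdsc_channels: int = 16
    dropout: float = 0.1
    se_reduction: int = 16
    se_enabled: bool = True
    input_length: int = 7200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.dilations) == len(self.strides) == len(self.channels)):
            raise ValueError("dilations, strides and channels must align")
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")

    @property
    def mdsc_out_channels(self) -> int:
        return self.mdsc_channels * len(self.mdsc_kernel_sizes)

    @property
    def out_channels(self) -> int:
        return self.channels[-1]

    def output_lengths(self) -> List[int]:
        """Sequence length after MDSC and after each block (ceil division)."""
        lengths = [self.input_length]
        n = self.input_length
        for s in self.strides:
            n = -(-n // s)
            lengths.append(n)
        return lengths

    @property
    def out_length(self) -> int:
        return self.output_lengths()[-1]


def receptive_field(cfg: Optional[BackboneConfig] = None) -> int:
    """Receptive-field size 1 + 2*(k-1)*sum(dilations) of the block stack.

    Counts the span covered by the ten dilated convolutions (two per block)
    in their own, unstrided coordinates; strides and the front end extend
    the raw-input span well beyond this number.
    """
    cfg = cfg or BackboneConfig()
    return 1 + 2 * (cfg.kernel_size - 1) * sum(cfg.dilations)


class MDSC(Module):
    """Multi-scale depthwise-separable convolution front end.

    Parallel branches with different kernel sizes, channel-concatenated and
    ReLU-activated; sequence length is preserved (left padding keeps the
    branches causal).
    """

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.branches = [
            DepthwiseSeparableConv1d(1, cfg.mdsc_channels, k, rng)
            for k in cfg.mdsc_kernel_sizes
        ]

    def forward(self, x: Tensor, activate: bool = True) -> Tensor:
        if x.shape[-1] != 1:
            raise ValueError(f"MDSC expects a single input channel, got {x.shape[-1]}")
        y = concat([b(x) for b in self.branches], axis=-1)
        return y.relu() if activate else y


class SETCNBlock(Module):
    """Residual block: two dilated causal convolutions vs gated 1x1 shortcut.

    Main path: conv(k, d, stride) -> BN -> ReLU -> dropout ->
    conv(k, d, 1) -> BN -> ReLU -> dropout.  Shortcut: 1x1 convolution with
    the block stride, then an SE channel gate.  Output = ReLU(main + short).
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        kernel_size: int,
        dilation: int,
        stride: int,
        rng: np.random.Generator,
        dropout: float = 0.1,
        se_reduction: int = 16,
        se_enabled: bool = True,
    ):
        super().__init__()
        self.conv1 = CausalConv1d(n_in, n_out, kernel_size, rng, dilation, stride)
        self.bn1 = BatchNorm1d(n_out)
        self.drop1 = Dropout(dropout, rng)
        self.conv2 = CausalConv1d(n_out, n_out, kernel_size, rng, dilation, 1)
        self.bn2 = BatchNorm1d(n_out)
        self.drop2 = Dropout(dropout, rng)
        self.shortcut = CausalConv1d(n_in, n_out, 1, rng, 1, stride)
        self.se = SEBlock(n_out, rng, se_reduction) if se_enabled else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.drop1(self.bn1(self.conv1(x)).relu())
        h = self.drop2(self.bn2(self.conv2(h)).relu())
        s = self.shortcut(x)
        if self.se is not None:
            s = self.se(s)
        return (h + s).relu()


class SETCNBackbone(Module):
    """MDSC front end followed by the five residual SE-TCN blocks."""

    def __init__(self, cfg: BackboneConfig, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.mdsc = MDSC(cfg, rng)
        blocks = []
        n_in = cfg.mdsc_out_channels
        for d, s, c in zip(cfg.dilations, cfg.strides, cfg.channels):
            blocks.append(
                SETCNBlock(
                    n_in, c, cfg.kernel_size, d, s, rng,
                    dropout=cfg.dropout,
                    se_reduction=cfg.se_reduction,
                    se_enabled=cfg.se_enabled,
                )
            )
            n_in = c
        self.blocks = blocks

    def forward(self, x, return_intermediate: bool = False):
        """Map (B, L, 1) signals to the latent (B, L/18, C_out) sequence."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 3 or x.shape[1] != self.cfg.input_length:
            raise ValueError(
                f"expected input shape (B, {self.cfg.input_length}, 1), got {x.shape}"
            )
        shapes = []
        h = self.mdsc(x)
        shapes.append(h.shape)
        for block in self.blocks:
            h = block(h)
            shapes.append(h.shape)
        if return_intermediate:
            return h, shapes
        return h
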