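"""Double coordinate attention (DCA) over H×W×C feature maps.

Coordinate attention keeps positional information that global average pooling
destroys: the map is pooled along *one* spatial axis only, squeezed through a
1×1 channel-reduction projection (factor r), passed through hard-swish, then
expanded back and squashed by a sigmoid into per-(row, channel) gates that
rescale the input.  DCA applies this twice in series — first pooling along
the width (preserving height-position information), then along the height —
with independent weights, and never changes the input shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DCAWeights", "coord_pool", "hard_swish", "dca_forward"]


def hard_swish(x):
    """x · ReLU6(x + 3) / 6, elementwise; ReLU6 = min(max(·, 0), 6)."""
    x = np.asarray(x, dtype=np.float64)
    return x * np.minimum(np.maximum(x + 3.0, 0.0), 6.0) / 6.0


def coord_pool(x: np.ndarray, axis: str) -> np.ndarray:
    """Direction-wise average pooling of an H×W×C map.

    axis='height' keeps height resolved (mean over width, shape H×1×C);
    axis='width' keeps width resolved (mean over height, shape 1×W×C).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"expected H×W×C feature map, got shape {x.shape}")
    if axis == "height":
        return x.mean(axis=1, keepdims=True)
    if axis == "width":
        return x.mean(axis=0, keepdims=True)
    raise ValueError(f"axis must be 'height' or 'width', got {axis!r}")


def _reduced_channels(c: int, r: int) -> int:
    return max(1, math.ceil(c / r))


@dataclass
class DCAWeights:
    """Projection weights of the two serial attention sub-modules.

    Each sub-module holds a channel-reduction 1×1 projection (C → ⌈C/r⌉) and
    an expansion back to C.  Weight matrices act on the channel axis of the
    pooled map; biases are per output channel.
    """

    reduce_h: np.ndarray   # (Cr, C)
    bias_rh: np.ndarray    # (Cr,)
    expand_h: np.ndarray   # (C, Cr)
    bias_eh: np.ndarray    # (C,)
    reduce_w: np.ndarray
    bias_rw: np.ndarray
    expand_w: np.ndarray
    bias_ew: np.ndarray
    r: int = 16

    @property
    def channels(self) -> int:
        return self.reduce_h.shape[1]

    @classmethod
    def init(cls, channels: int, r: int = 16, seed: int = 0) -> "DCAWeights":
        """Seeded He-style initialisation with zero biases."""
        rng = np.random.default_rng(seed)
        cr = _reduced_channels(channels, r)

        def w(fan_out, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_out, fan_in))

        return cls(
            reduce_h=w(cr, channels), bias_rh=np.zeros(cr),
            expand_h=w(channels, cr), bias_eh=np.zeros(channels),
            reduce_w=w(cr, channels), bias_rw=np.zeros(cr),
            expand_w=w(channels, cr), bias_ew=np.zeros(channels),
            r=r,
        )

    @classmethod
    def zeros(cls, channels: int, r: int = 16) -> "DCAWeights":
        cr = _reduced_channels(channels, r)
        return cls(
            reduce_h=np.zeros((cr, channels)), bias_rh=np.zeros(cr),
            expand_h=np.zeros((channels, cr)), bias_eh=np.zeros(channels),
            reduce_w=np.zeros((cr, channels)), bias_rw=np.zeros(cr),
            expand_w=np.zeros((channels, cr)), bias_ew=np.zeros(channels),
            r=r,
        )

    def save(self, path) -> None:
        """Export as a flat named-array archive (numpy .npz)."""
        np.savez(path, r=np.array(self.r), reduce_h=self.reduce_h,
                 bias_rh=self.bias_rh, expand_h=self.expand_h,
                 bias_eh=self.bias_eh, reduce_w=self.reduce_w,
                 bias_rw=self.bias_rw, expand_w=self.expand_w,
                 bias_ew=self.bias_ew)

    @classmethod
    def load(cls, path) -> "DCAWeights":
        with np.load(path) as z:
            return cls(reduce_h=z["reduce_h"], bias_rh=z["bias_rh"],
                       expand_h=z["expand_h"], bias_eh=z["bias_eh"],
                       reduce_w=z["reduce_w"], bias_rw=z["bias_rw"],
                       expand_w=z["expand_w"], bias_ew=z["bias_ew"],
                       r=int(z["r"]))


def _gate(pooled: np.ndarray, w_red, b_red, w_exp, b_exp) -> np.ndarray:
    """Reduction → hard-swish → expansion → sigmoid on a pooled map."""
    f = hard_swish(pooled @ w_red.T + b_red)
    return 1.0 / (1.0 + np.exp(-(f @ w_exp.T + b_exp)))


def dca_forward(x: np.ndarray, weights: DCAWeights) -> np.ndarray:
    """Apply the two serial coordinate-attention sub-modules to x (H×W×C).

    Sub-module 1 pools over width, gates per (height, channel); sub-module 2
    repeats the computation on the intermediate result pooling over height,
    gating per (width, channel).  Output shape equals input shape and every
    gate lies strictly in (0, 1).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"expected H×W×C feature map, got shape {x.shape}")
    if x.shape[2] != weights.channels:
        raise ValueError(
            f"channel mismatch: map has {x.shape[2]} channels, "
            f"weights expect {weights.channels}")
    g_h = _gate(coord_pool(x, "height"),
                weights.reduce_h, weights.bias_rh,
                weights.expand_h, weights.bias_eh)          # H×1×C
    mid = x * g_h
    g_w = _gate(coord_pool(mid, "width"),
                weights.reduce_w, weights.bias_rw,
                weights.expand_w, weights.bias_ew)          # 1×W×C
    return mid * g_w
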