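"""Axis-aligned box geometry and the CIoU / inner-IoU / AICI regression losses.

Boxes are axis-aligned rectangles in *center format* ``(cx, cy, w, h)`` with
continuous (sub-pixel) coordinates.  All functions are vectorised: they accept
a single :class:`Box`, an ndarray of shape ``(..., 4)``, or — for the
differentiable path used by the training harness — a tuple of four
:class:`~stenoskit.autodiff.Tensor` components.

The loss family implemented here:

``ciou_loss``
    ``1 − IoU + ρ²(b, b_gt)/c² + α·υ`` where ρ² is the squared distance
    between box centers, c² the squared diagonal of the smallest enclosing
    box, υ the aspect-ratio consistency term and α its IoU-dependent weight.

``inner_iou``
    IoU of *auxiliary* boxes that share the originals' centers but have their
    width and height scaled by ``ratio``.  A ratio > 1 yields non-zero overlap
    (hence gradient) for near-miss small targets where plain IoU is flat zero.

``aici_loss``
    Adaptive inner-CIoU: ``1 − IoU_inner + τ·ρ²/c² + ψ·α·υ`` with nonnegative
    weights ψ and τ (learnable in the harness via a softplus reparameterisation).
    With ``ratio=1, ψ=τ=1`` it reduces exactly to ``ciou_loss``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

EPS = 1e-9

__all__ = [
    "Box",
    "AICIParams",
    "iou",
    "upsilon_alpha",
    "ciou_loss",
    "inner_iou",
    "aici_loss",
    "rasterized_iou",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in center format, continuous pixel coordinates."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.w < 0 or self.h < 0:
            raise ValueError(f"invalid box: negative size w={self.w} h={self.h}")

    @property
    def left(self) -> float:
        return self.cx - self.w / 2

    @property
    def right(self) -> float:
        return self.cx + self.w / 2

    @property
    def top(self) -> float:
        return self.cy - self.h / 2

    @property
    def bottom(self) -> float:
        return self.cy + self.h / 2

    @property
    def area(self) -> float:
        return self.w * self.h

    def as_array(self) -> np.ndarray:
        return np.array([self.cx, self.cy, self.w, self.h], dtype=np.float64)

    @classmethod
    def from_corners(cls, left: float, top: float, right: float,
                     bottom: float) -> "Box":
        return cls((left + right) / 2, (top + bottom) / 2,
                   right - left, bottom - top)


@dataclass
class AICIParams:
    """Weights of the adaptive inner-CIoU loss.

    ratio : scale of the auxiliary (inner) boxes, > 0; default 1.1.
    psi   : nonnegative weight on the aspect-consistency term α·υ; init 0.5.
    tau   : nonnegative weight on the center-distance term ρ²/c²; init 0.5.
    learnable : whether the harness treats psi/tau as trainable (they are then
        stored unconstrained and mapped through softplus to stay nonnegative).
    """

    ratio: float = 1.1
    psi: float = 0.5
    tau: float = 0.5
    learnable: bool = False

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError(f"ratio must be positive, got {self.ratio}")
        if self.psi < 0 or self.tau < 0:
            raise ValueError("psi and tau must be nonnegative")


# ---------------------------------------------------------------------------
# input normalisation
# ---------------------------------------------------------------------------

def _components(box, validate: bool = True):
    """Split a Box / (...,4) array / 4-tuple of Tensors into cx, cy, w, h."""
    if isinstance(box, Box):
        return box.cx, box.cy, box.w, box.h
    if isinstance(box, tuple) and len(box) == 4:
        return box
    arr = np.asarray(box, dtype=np.float64)
    if arr.shape[-1] != 4:
        raise ValueError(f"expected (..., 4) box array, got shape {arr.shape}")
    cx, cy, w, h = (arr[..., i] for i in range(4))
    if validate and (np.any(w < 0) or np.any(h < 0)):
        raise ValueError("invalid box: negative width or height")
    return cx, cy, w, h


def _maybe_scalar(x):
    if isinstance(x, Tensor):
        return x
    x = np.asarray(x)
    return x.item() if x.ndim == 0 else x


# ---------------------------------------------------------------------------
# IoU and its relatives
# ---------------------------------------------------------------------------

def _iou_from_corners(l1, t1, r1, b1, l2, t2, r2, b2):
    iw = ad.maximum(ad.minimum(r1, r2) - ad.maximum(l1, l2), 0.0)
    ih = ad.maximum(ad.minimum(b1, b2) - ad.maximum(t1, t2), 0.0)
    inter = iw * ih
    union = (r1 - l1) * (b1 - t1) + (r2 - l2) * (b2 - t2) - inter
    return inter / ad.maximum(union, EPS)


def iou(pred, gt):
    """Intersection over union of two boxes in [0, 1]; symmetric; 0 for
    degenerate boxes with empty union."""
    px, py, pw, ph = _components(pred)
    gx, gy, gw, gh = _components(gt)
    return _maybe_scalar(_iou_from_corners(
        px - pw / 2, py - ph / 2, px + pw / 2, py + ph / 2,
        gx - gw / 2, gy - gh / 2, gx + gw / 2, gy + gh / 2))


def upsilon_alpha(pred, gt, iou_value):
    """Aspect-ratio consistency term υ and its weight α.

    υ = (4/π²)(arctan(w_gt/h_gt) − arctan(w/h))²,
    α = υ / ((1 − IoU) + υ),  with α = 0 when υ = 0.
    """
    px, py, pw, ph = _components(pred)
    gx, gy, gw, gh = _components(gt)
    for h, w in ((ph, pw), (gh, gw)):
        if not isinstance(h, Tensor) and np.any(np.asarray(h) <= 0):
            raise ValueError("degenerate aspect: box height must be positive")
        if not isinstance(w, Tensor) and np.any(np.asarray(w) <= 0):
            raise ValueError("degenerate aspect: box width must be positive")
    ups = (4.0 / np.pi ** 2) * (ad.arctan(gw / gh) - ad.arctan(pw / ph)) ** 2
    alpha = ups / ad.maximum((1.0 - iou_value) + ups, EPS)
    return _maybe_scalar(ups), _maybe_scalar(alpha)


def ciou_loss(pred, gt, return_terms: bool = False):
    """Complete-IoU loss: 1 − IoU + ρ²/c² + αυ; exactly 0 when pred == gt."""
    i = iou(pred, gt)
    dist = _center_distance_term(pred, gt)
    ups, alpha = upsilon_alpha(pred, gt, i)
    loss = (1.0 - i) + dist + alpha * ups
    if return_terms:
        return loss, {"iou": i, "distance": _maybe_scalar(dist),
                      "aspect": _maybe_scalar(alpha * ups)}
    return _maybe_scalar(loss)


def _center_distance_term(pred, gt):
    """ρ²(b, b_gt) / c² on the original (unscaled) boxes, with an ε guard."""
    px, py, pw, ph = _components(pred)
    gx, gy, gw, gh = _components(gt)
    rho2 = (px - gx) ** 2 + (py - gy) ** 2
    cw = ad.maximum(px + pw / 2, gx + gw / 2) - ad.minimum(px - pw / 2, gx - gw / 2)
    ch = ad.maximum(py + ph / 2, gy + gh / 2) - ad.minimum(py - ph / 2, gy - gh / 2)
    c2 = cw ** 2 + ch ** 2
    return rho2 / ad.maximum(c2, EPS)


def inner_corners(box, ratio: float):
    """Corners (l, t, r, b) of the auxiliary box: same center, dims scaled by
    ``ratio``."""
    cx, cy, w, h = _components(box)
    hw = w * (ratio / 2.0)
    hh = h * (ratio / 2.0)
    return cx - hw, cy - hh, cx + hw, cy + hh


def inner_iou(pred, gt, ratio: float = 1.1):
    """IoU of the ratio-scaled auxiliary boxes; equals iou() at ratio = 1.

    The raw intersection formula can go negative for disjoint auxiliary
    boxes; it is clamped at zero (an area cannot be negative).
    """
    if not np.isscalar(ratio) or ratio <= 0:
        raise ValueError(f"ratio must be a positive scalar, got {ratio}")
    pl, pt, pr, pb = inner_corners(pred, ratio)
    gl, gt_, gr, gb = inner_corners(gt, ratio)
    return _maybe_scalar(_iou_from_corners(pl, pt, pr, pb, gl, gt_, gr, gb))


def aici_loss(pred, gt, params: AICIParams | None = None, *,
              ratio=None, psi=None, tau=None,
              alpha_from_inner: bool = True, return_terms: bool = False):
    """Adaptive inner-CIoU loss: 1 − IoU_inner + τ·ρ²/c² + ψ·αυ.

    ρ²/c² is computed on the original (unscaled) boxes; α is computed from
    IoU_inner by default (``alpha_from_inner=False`` uses plain IoU instead).
    ``psi``/``tau`` may be Tensors so the harness can learn them.  Reduces
    exactly to :func:`ciou_loss` at ratio = 1, ψ = τ = 1.
    """
    if params is None:
        params = AICIParams()
    ratio = params.ratio if ratio is None else ratio
    psi = params.psi if psi is None else psi
    tau = params.tau if tau is None else tau
    ii = inner_iou(pred, gt, ratio)
    dist = _center_distance_term(pred, gt)
    alpha_iou = ii if alpha_from_inner else iou(pred, gt)
    ups, alpha = upsilon_alpha(pred, gt, alpha_iou)
    loss = (1.0 - ii) + tau * dist + psi * (alpha * ups)
    if return_terms:
        return loss, {"inner_iou": _maybe_scalar(ii),
                      "distance": _maybe_scalar(dist),
                      "aspect": _maybe_scalar(alpha * ups)}
    return _maybe_scalar(loss)


# ---------------------------------------------------------------------------
# rasterization oracle (kept here so tests and the acceptance script share it)
# ---------------------------------------------------------------------------

def rasterized_iou(a: Box, b: Box, cells: int = 400) -> float:
    """Grid-counting IoU approximation, independent of the analytic path.

    Overlays a ``cells × cells`` grid on the joint bounding region and counts
    cell centers falling inside each rectangle.  Accuracy ~ O(1/cells).
    """
    left = min(a.left, b.left)
    right = max(a.right, b.right)
    top = min(a.top, b.top)
    bottom = max(a.bottom, b.bottom)
    if right <= left or bottom <= top:
        return 0.0
    xs = left + (np.arange(cells) + 0.5) * (right - left) / cells
    ys = top + (np.arange(cells) + 0.5) * (bottom - top) / cells
    X, Y = np.meshgrid(xs, ys)

    def inside(r: Box):
        return (X >= r.left) & (X <= r.right) & (Y >= r.top) & (Y <= r.bottom)

    ia, ib = inside(a), inside(b)
    union = np.count_nonzero(ia | ib)
    if union == 0:
        return 0.0
    return np.count_nonzero(ia & ib) / union
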