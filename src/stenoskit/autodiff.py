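"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the primitives the rest of the package needs: elementwise
arithmetic, ``maximum``/``minimum`` (for clamps), ``arctan`` (aspect-ratio
penalty), ``exp``/``log``/``sigmoid``, reductions, matmul, a strided 2-D
convolution, and an Adam optimizer.  Everything is double precision and
single-threaded; the engine is sized for the desk-scale models in
:mod:`stenoskit.harness`, not for large networks.

The dispatch helpers (:func:`maximum`, :func:`arctan`, ...) accept either
plain ndarrays or :class:`Tensor` objects, so the same loss code in
:mod:`stenoskit.boxloss` runs on both.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "maximum",
    "minimum",
    "arctan",
    "exp",
    "log",
    "sigmoid",
    "softplus",
    "hard_swish",
    "conv2d",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping.

    Builds a DAG of operations; ``backward()`` on a scalar Tensor fills
    ``.grad`` on every reachable Tensor with ``requires_grad=True``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # make ndarray + Tensor defer to Tensor

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- autodiff core -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (many GD steps)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data ** 2)
        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bwd
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)
        out._backward = bwd
        return out


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


# ---------------------------------------------------------------------------
# dispatch helpers: work on Tensor or ndarray alike
# ---------------------------------------------------------------------------

def _is_t(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def maximum(a, b):
    if not _is_t(a, b):
        return np.maximum(a, b)
    a, b = Tensor._lift(a), Tensor._lift(b)
    mask = a.data >= b.data  # ties route to the first argument
    out = Tensor(np.maximum(a.data, b.data), parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(g * mask)
        if b.requires_grad:
            b._accum(g * (~mask))
    out._backward = bwd
    return out


def minimum(a, b):
    if not _is_t(a, b):
        return np.minimum(a, b)
    a, b = Tensor._lift(a), Tensor._lift(b)
    mask = a.data <= b.data
    out = Tensor(np.minimum(a.data, b.data), parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(g * mask)
        if b.requires_grad:
            b._accum(g * (~mask))
    out._backward = bwd
    return out


def arctan(x):
    if not _is_t(x):
        return np.arctan(x)
    out = Tensor(np.arctan(x.data), parents=(x,))
    out._backward = lambda g: x._accum(g / (1.0 + x.data ** 2))
    return out


def exp(x):
    if not _is_t(x):
        return np.exp(x)
    out = Tensor(np.exp(x.data), parents=(x,))
    out._backward = lambda g: x._accum(g * out.data)
    return out


def log(x):
    if not _is_t(x):
        return np.log(x)
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = lambda g: x._accum(g / x.data)
    return out


def sigmoid(x):
    if not _is_t(x):
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out


def softplus(x):
    """log(1 + e^x), numerically stable; maps R onto (0, inf)."""
    if not _is_t(x):
        x = np.asarray(x, dtype=np.float64)
        return np.logaddexp(0.0, x)
    s = np.logaddexp(0.0, x.data)
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x._accum(g / (1.0 + np.exp(-x.data)))
    return out


def softplus_inverse(y):
    """Real x with softplus(x) = y, for y > 0."""
    y = np.asarray(y, dtype=np.float64)
    return y + np.log(-np.expm1(-y))


def hard_swish(x):
    """x * ReLU6(x + 3) / 6 with ReLU6 = min(max(., 0), 6)."""
    return x * minimum(maximum(x + 3.0, 0.0), 6.0) * (1.0 / 6.0)


def bce_with_logits(z, y):
    """Elementwise binary cross-entropy on logits z against targets y."""
    # max(z,0) - z*y + log(1 + exp(-|z|)), stable for large |z|
    absz = maximum(z, -1.0 * z) if _is_t(z) else np.abs(z)
    return maximum(z, 0.0) - z * y + log(1.0 + exp(-1.0 * absz))


# ---------------------------------------------------------------------------
# 2-D convolution (NCHW) as a primitive
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Strided cross-correlation of x (B,C,H,W) with w (O,C,k,k)."""
    x = Tensor._lift(x)
    w = Tensor._lift(w)
    B, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding))) if padding else x.data
    Ho = (xp.shape[2] - kh) // stride + 1
    Wo = (xp.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # B,C,Ho,Wo,kh,kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(O, C * kh * kw)
    out_d = cols @ wmat.T
    if b is not None:
        out_d = out_d + Tensor._lift(b).data
    out_d = out_d.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, Tensor._lift(b))
    out = Tensor(out_d, parents=parents)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, O)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.data.shape))
        if b is not None and parents[2].requires_grad:
            parents[2]._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(B, Ho, Wo, C, kh, kw)
            dxp = np.zeros_like(xp)
            for di in range(kh):
                for dj in range(kw):
                    dxp[:, :, di:di + Ho * stride:stride,
                        dj:dj + Wo * stride:stride] += dcols[:, :, :, :, di, dj
                                                             ].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: Sequence[Tensor], lr: float = 0.002,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def grad_check(f: Callable[[Tensor], Tensor], x: np.ndarray,
               eps: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Analytic vs central-difference gradient of scalar f at x (testing aid)."""
    t = Tensor(x.copy(), requires_grad=True)
    f(t).backward()
    num = np.zeros_like(x, dtype=np.float64)
    flat = x.astype(np.float64).ravel()
    for i in range(flat.size):
        for sgn in (+1, -1):
            pert = flat.copy()
            pert[i] += sgn * eps
            val = f(Tensor(pert.reshape(x.shape))).data.item()
            num.ravel()[i] += sgn * val / (2 * eps)
    return t.grad, num
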