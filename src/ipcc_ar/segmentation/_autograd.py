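"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery to express and train a small encoder-decoder
segmentation network: 3x3/1x1 convolutions (im2col), ReLU, sigmoid, 2x2 max
pooling, nearest-neighbor upsampling, channel concatenation, and a soft Dice
loss whose gradient is supplied in closed form. Tensors are unbatched
``(channels, height, width)`` arrays — the training regime is batch size
one, so batching machinery would buy nothing.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "relu",
    "sigmoid",
    "maxpool2",
    "upsample2",
    "concat",
    "dice_loss",
]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data: np.ndarray, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) node."""
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(C,H,W) padded-same -> columns (C*kh*kw, H*W)."""
    c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # windows: (C, H, W, kh, kw) -> (C, kh, kw, H*W)
    return windows.transpose(0, 3, 4, 1, 2).reshape(c * kh * kw, h * w)


def _col2im(cols: np.ndarray, shape: tuple[int, int, int], kh: int, kw: int):
    """Adjoint of :func:`_im2col`: scatter-add columns back to an image."""
    c, h, w = shape
    ph, pw = kh // 2, kw // 2
    xp = np.zeros((c, h + 2 * ph, w + 2 * pw))
    cols = cols.reshape(c, kh, kw, h, w)
    for i in range(kh):
        for j in range(kw):
            xp[:, i : i + h, j : j + w] += cols[:, i, j]
    return xp[:, ph : ph + h, pw : pw + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padding 2-D convolution; weight is (C_out, C_in, kh, kw)."""
    co, ci, kh, kw = weight.shape
    _, h, w = x.shape
    cols = _im2col(x.data, kh, kw)
    wmat = weight.data.reshape(co, ci * kh * kw)
    out = (wmat @ cols).reshape(co, h, w) + bias.data[:, None, None]

    def backward(g: np.ndarray) -> None:
        gmat = g.reshape(co, h * w)
        weight._accumulate((gmat @ cols.T).reshape(weight.shape))
        bias._accumulate(g.sum(axis=(1, 2)))
        if x.requires_grad or x._parents:
            x._accumulate(_col2im(wmat.T @ gmat, x.data.shape, kh, kw))

    return _node(out, (x, weight, bias), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * mask)

    return _node(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * y * (1.0 - y))

    return _node(y, (x,), backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling; ties resolve to the first element (deterministic)."""
    c, h, w = x.shape
    blocks = x.data.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4)
    flat = blocks.reshape(c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=3)
    out = np.take_along_axis(flat, idx[..., None], axis=3)[..., 0]

    def backward(g: np.ndarray) -> None:
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=3)
        gx = (
            gflat.reshape(c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 3, 2, 4)
            .reshape(c, h, w)
        )
        x._accumulate(gx)

    return _node(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x upsampling."""
    out = x.data.repeat(2, axis=1).repeat(2, axis=2)

    def backward(g: np.ndarray) -> None:
        c, h2, w2 = g.shape
        gx = g.reshape(c, h2 // 2, 2, w2 // 2, 2).sum(axis=(2, 4))
        x._accumulate(gx)

    return _node(out, (x,), backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    ca = a.shape[0]

    def backward(g: np.ndarray) -> None:
        a._accumulate(g[:ca])
        b._accumulate(g[ca:])

    return _node(np.concatenate([a.data, b.data], axis=0), (a, b), backward)


def dice_loss(prob: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """Soft Dice loss ``1 - (2*sum(p*y)+eps) / (sum(p)+sum(y)+eps)``.

    The gradient with respect to the probabilities is supplied in closed
    form; ``eps`` smooths the all-background case.
    """
    p = prob.data
    y = np.asarray(target, dtype=float)
    inter = float((p * y).sum())
    denom = float(p.sum() + y.sum()) + eps
    loss = 1.0 - (2.0 * inter + eps) / denom

    def backward(g: np.ndarray) -> None:
        dp = -(2.0 * y * denom - (2.0 * inter + eps)) / (denom * denom)
        prob._accumulate(g * dp)

    return _node(np.array(loss), (prob,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g: np.ndarray) -> None:
        a._accumulate(g)
        b._accumulate(g)

    return _node(a.data + b.data, (a, b), backward)


def scale(x: Tensor, k: float) -> Tensor:
    def backward(g: np.ndarray) -> None:
        x._accumulate(g * k)

    return _node(x.data * k, (x,), backward)
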