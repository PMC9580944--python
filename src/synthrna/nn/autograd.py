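"""Tiny reverse-mode autodiff over numpy arrays.

Supports exactly the operations the bundled models need: broadcasting
arithmetic, matmul, pointwise nonlinearities, reductions, reshapes,
concatenation, same-padding 1-D/2-D convolution, and a fused
sigmoid+binary-cross-entropy loss.  Gradients are checked numerically in
the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
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
    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, requires_grad=False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _prev
        )
        self._prev = _prev
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph --------------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ---------------------------------------------------------

    def _lift(self, other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def matmul(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += g @ np.swapaxes(other.data, -1, -2)
            if other.requires_grad:
                other.grad += _unbroadcast(
                    np.swapaxes(self.data, -1, -2) @ g, other.data.shape
                )

        out._backward = bw
        return out

    __matmul__ = matmul

    # -- nonlinearities -----------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * (self.data > 0)

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * s * (1.0 - s)

        out._backward = bw
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * (1.0 - t * t)

        out._backward = bw
        return out

    # -- shape --------------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)

        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self.grad += g.transpose(inv)

        out._backward = bw
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _prev=(self,))

        def bw(g):
            if self.requires_grad:
                np.add.at(self.grad, key, g)

        out._backward = bw
        return out

    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                if axis is None:
                    self.grad += g
                else:
                    self.grad += np.expand_dims(g, axis)

        out._backward = bw
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)


def concat(tensors, axis=0):
    tensors = list(tensors)
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _prev=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t.grad += g[tuple(sl)]

    out._backward = bw
    return out


def stack(tensors, axis=0):
    tensors = list(tensors)
    out = Tensor(
        np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors)
    )

    def bw(g):
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t.grad += np.take(g, k, axis=axis)

    out._backward = bw
    return out


# -- convolution ------------------------------------------------------------


def _patches2d(x: np.ndarray, k: int) -> np.ndarray:
    """(B,C,H,W) -> (B,H,W,C,k,k) same-padded sliding windows."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return win.transpose(0, 2, 3, 1, 4, 5)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding 2-D convolution; x (B,C,H,W), w (Cout,C,k,k)."""
    B, C, H, W = x.data.shape
    Cout, _, k, _ = w.data.shape
    patches = _patches2d(x.data, k).reshape(B * H * W, C * k * k)
    out_data = (patches @ w.data.reshape(Cout, -1).T).reshape(B, H, W, Cout)
    out_data = out_data.transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def bw(g):
        go = g.transpose(0, 2, 3, 1).reshape(B * H * W, Cout)
        if w.requires_grad:
            w.grad += (go.T @ patches).reshape(w.data.shape)
        if b is not None and b.requires_grad:
            b.grad += go.sum(axis=0)
        if x.requires_grad:
            # full correlation of grad with flipped kernels
            wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gp = _patches2d(g, k).reshape(B * H * W, Cout * k * k)
            gx = (gp @ wf.reshape(C, -1).T).reshape(B, H, W, C)
            x.grad += gx.transpose(0, 3, 1, 2)

    out._backward = bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding 1-D convolution; x (B,C,L), w (Cout,C,k)."""
    xb = x.reshape(*x.data.shape, 1)
    # reuse conv2d with a k x 1 kernel on an L x 1 image
    k = w.data.shape[2]
    w2 = w.reshape(*w.data.shape, 1)
    out = _conv2d_k1(xb, w2, b, k)
    return out.reshape(out.data.shape[0], out.data.shape[1], -1)


def _conv2d_k1(x, w, b, k):
    B, C, H, _ = x.data.shape
    Cout = w.data.shape[0]
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, 1), axis=(2, 3))
    patches = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H, C * k)
    out_data = (patches @ w.data.reshape(Cout, -1).T).reshape(B, H, 1, Cout)
    out_data = out_data.transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def bw(g):
        go = g.transpose(0, 2, 3, 1).reshape(B * H, Cout)
        if w.requires_grad:
            w.grad += (go.T @ patches).reshape(w.data.shape)
        if b is not None and b.requires_grad:
            b.grad += go.sum(axis=0)
        if x.requires_grad:
            wf = w.data[:, :, ::-1, :].transpose(1, 0, 2, 3)
            gp_src = np.pad(g, ((0, 0), (0, 0), (p, p), (0, 0)))
            gwin = np.lib.stride_tricks.sliding_window_view(
                gp_src, (k, 1), axis=(2, 3)
            )
            gp = gwin.transpose(0, 2, 3, 1, 4, 5).reshape(B * H, Cout * k)
            gx = (gp @ wf.reshape(C, -1).T).reshape(B, H, 1, C)
            x.grad += gx.transpose(0, 3, 1, 2)

    out._backward = bw
    return out


# -- losses -----------------------------------------------------------------


def bce_with_logits(
    logits: Tensor,
    targets: np.ndarray,
    mask: np.ndarray | None = None,
    pos_weight: float = 1.0,
) -> Tensor:
    """Mean binary cross-entropy over (optionally masked) entries.

    ``pos_weight`` rescales the positive-class term (useful for the very
    sparse pair matrices).
    """
    z = logits.data
    t = np.asarray(targets, dtype=np.float64)
    m = np.ones_like(z) if mask is None else np.asarray(mask, dtype=np.float64)
    if pos_weight != 1.0:
        m = m * (1.0 + (pos_weight - 1.0) * t)
    nm = m.sum()
    # stable: max(z,0) - z*t + log(1+exp(-|z|))
    loss = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))) * m
    out = Tensor(loss.sum() / nm, _prev=(logits,))

    def bw(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            logits.grad += g * (s - t) * m / nm

    out._backward = bw
    return out
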