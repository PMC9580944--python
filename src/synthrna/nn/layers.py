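"""Neural layers built on the autograd tensor."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv1d, conv2d


class Module:
    def parameters(self) -> list[Tensor]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state) -> None:
        for p, d in zip(self.parameters(), state, strict=True):
            p.data = d.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng, *shape):
    fan_in = int(np.prod(shape[1:])) or shape[0]
    fan_out = shape[0]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)


class Dense(Module):
    def __init__(self, n_in, n_out, rng):
        self.w = _glorot(rng, n_out, n_in)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w.transpose(1, 0) + self.b


class Conv1d(Module):
    def __init__(self, c_in, c_out, k, rng):
        self.w = _glorot(rng, c_out, c_in, k)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:  # x (B,C,L)
        return conv1d(x, self.w, self.b)


class Conv2d(Module):
    def __init__(self, c_in, c_out, k, rng):
        self.w = _glorot(rng, c_out, c_in, k, k)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:  # x (B,C,H,W)
        return conv2d(x, self.w, self.b)


class LSTM(Module):
    """Unidirectional LSTM over (T, B, C) input, returns (T, B, H)."""

    def __init__(self, n_in, n_hidden, rng, reverse=False):
        self.n_hidden = n_hidden
        self.reverse = reverse
        self.wx = _glorot(rng, 4 * n_hidden, n_in)
        self.wh = _glorot(rng, 4 * n_hidden, n_hidden)
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        T, B, _ = x.data.shape
        H = self.n_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        steps = range(T - 1, -1, -1) if self.reverse else range(T)
        outs = [None] * T
        wxT = self.wx.transpose(1, 0)
        whT = self.wh.transpose(1, 0)
        for t in steps:
            z = x[t] @ wxT + h @ whT + self.b
            i = z[:, 0:H].sigmoid()
            f = z[:, H : 2 * H].sigmoid()
            g = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs[t] = h
        from .autograd import stack

        return stack(outs, axis=0)


class BiLSTM(Module):
    def __init__(self, n_in, n_hidden, rng):
        self.fwd = LSTM(n_in, n_hidden, rng)
        self.bwd = LSTM(n_in, n_hidden, rng, reverse=True)

    def forward(self, x: Tensor) -> Tensor:
        return concat([self.fwd(x), self.bwd(x)], axis=2)


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
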