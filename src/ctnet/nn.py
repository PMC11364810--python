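"""Neural-network layers and the Adam optimizer on top of :mod:`ctnet.autograd`.

Layers follow the usual module pattern: ``parameters()`` walks the tree,
``train()/eval()`` toggles dropout and batch-norm statistics.  Weight layout
conventions match the common deep-learning ones (conv weights
``(Cout, Cin/groups, kh, kw)``, linear weights ``(in, out)``).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, avg_pool_w, conv2d, matmul

DTYPE = np.float32


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _submodules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                yield from (m for m in v if isinstance(m, Module))

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._submodules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # weight (de)serialization: a flat dict of numpy arrays, insertion order
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"p{i}"] = p.data.copy()
        for j, b in enumerate(self._buffers()):
            out[f"b{j}"] = b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = state[f"p{i}"].astype(p.data.dtype).reshape(p.data.shape)
        for j, b in enumerate(self._buffers()):
            b[...] = state[f"b{j}"]

    def _buffers(self):
        bufs = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                bufs.extend(v._buffers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        bufs.extend(item._buffers())
        return bufs


def count_parameters(module: Module) -> int:
    """Number of trainable scalars (batch-/layer-norm affine terms included)."""
    return int(sum(p.data.size for p in module.parameters()))


class Conv2d(Module):
    """Stride-1 2-D convolution, optional grouping, optional bias.

    ``padding`` is either ``(top, bottom, left, right)`` or the string
    ``"same-w"`` for zero padding that preserves the time (last) axis —
    asymmetric for even kernels (``(k-1)//2`` left, ``k//2`` right).
    """

    def __init__(self, cin, cout, kernel, padding=(0, 0, 0, 0), groups=1,
                 bias=False, rng=None):
        super().__init__()
        kh, kw = kernel
        if padding == "same-w":
            padding = (0, 0, (kw - 1) // 2, kw // 2)
        self.pad = tuple(padding)
        self.groups = groups
        rng = rng or np.random.default_rng()
        fan_in = (cin // groups) * kh * kw
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound, (cout, cin // groups, kh, kw)).astype(DTYPE),
            requires_grad=True)
        self.bias = (Tensor(np.zeros(cout, DTYPE), requires_grad=True)
                     if bias else None)

    def __call__(self, x: Tensor) -> Tensor:
        y = conv2d(x, self.weight, pad=self.pad, groups=self.groups)
        if self.bias is not None:
            y = y + self.bias.reshape(1, -1, 1, 1)
        return y


class Linear(Module):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(n_in)
        self.weight = Tensor(rng.uniform(-bound, bound, (n_in, n_out)).astype(DTYPE),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class BatchNorm2d(Module):
    """Per-channel batch normalization over (B, H, W) with running statistics."""

    def __init__(self, num_features, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features, DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, DTYPE), requires_grad=True)
        self.running_mean = np.zeros(num_features, DTYPE)
        self.running_var = np.ones(num_features, DTYPE)

    def _buffers(self):
        return [self.running_mean, self.running_var]

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data * (n / max(n - 1, 1))
            self.running_mean[...] = ((1 - m) * self.running_mean
                                      + m * mu.data.reshape(-1))
            self.running_var[...] = ((1 - m) * self.running_var
                                     + m * unbiased.reshape(-1))
            xhat = xc / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mu)) / Tensor(sd)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class LayerNorm(Module):
    """Normalization over the last axis with learned affine terms."""

    def __init__(self, dim, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Randomness from ``rng``."""

    def __init__(self, p: float, rng=None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class AvgPoolW(Module):
    def __init__(self, p: int):
        super().__init__()
        self.p = p

    def __call__(self, x: Tensor) -> Tensor:
        return avg_pool_w(x, self.p)


class Adam:
    """Adam with bias-corrected first/second moments; no weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
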