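"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core the network is built on: a :class:`Tensor` wraps a
float32/float64 ndarray together with an optional gradient and a backward
closure.  The operation set is deliberately small — exactly what a
convolution + Transformer-encoder classifier needs — and every primitive has a
hand-written vector-Jacobian product.  Gradients are validated against central
finite differences in the test suite.

Conventions
-----------
* Graphs are built eagerly; ``Tensor.backward()`` runs a topological sweep.
* Broadcasting follows numpy; gradients are summed back over broadcast axes.
* Convolution and pooling operate on ``(B, C, H, W)`` arrays, stride 1 for
  convolution, non-overlapping windows for average pooling.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "matmul", "conv2d", "avg_pool_w", "softmax_lastdim",
           "gelu_exact"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (L encoder layers)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * p * self.data ** (p - 1)
        )
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape)
        )
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.transpose(inv)
        )
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -----------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * 0.5 / y)
        return out

    def erf(self):
        out = Tensor(_erf(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (2.0 / np.sqrt(np.pi)) * np.exp(-self.data ** 2)
        )
        return out

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        y = np.where(self.data > 0, self.data, neg)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * np.where(self.data > 0, 1.0, neg + alpha)
        )
        return out

def gelu_exact(x: Tensor) -> Tensor:
    """GELU(x) = x * Phi(x), Phi the standard-normal CDF via erf."""
    phi = ((x * (1.0 / np.sqrt(2.0))).erf() + 1.0) * 0.5
    return x * phi


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with numpy broadcasting on leading axes."""
    out = Tensor(a.data @ b.data, a.requires_grad or b.requires_grad, (a, b))

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(ga)
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(gb)

    out._backward = bw
    return out


def softmax_lastdim(x: Tensor) -> Tensor:
    """Numerically stable softmax over the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(y * (g - (g * y).sum(axis=-1, keepdims=True)))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B, C, H, W) -> contiguous (B, Ho, Wo, C*kh*kw) patch matrix."""
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # v: (B, C, Ho, Wo, kh, kw) -> (B, Ho, Wo, C, kh, kw)
    v = v.transpose(0, 2, 3, 1, 4, 5)
    b, ho, wo = v.shape[:3]
    return np.ascontiguousarray(v).reshape(b, ho, wo, -1)


def conv2d(x: Tensor, w: Tensor, pad: tuple[int, int, int, int] = (0, 0, 0, 0),
           groups: int = 1) -> Tensor:
    """Cross-correlation of ``x`` (B,Cin,H,W) with ``w`` (Cout,Cin/g,kh,kw).

    ``pad`` is (top, bottom, left, right) zero padding; stride is 1.
    """
    b, cin, h, wdt = x.data.shape
    cout, cin_g, kh, kw = w.data.shape
    pt, pb, pl, pr = pad
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    ho = h + pt + pb - kh + 1
    wo = wdt + pl + pr - kw + 1
    if groups == 1:
        cols = _im2col(xp, kh, kw)                      # (B,Ho,Wo,Cin*kh*kw)
        wm = w.data.reshape(cout, -1)
        y = cols @ wm.T                                  # (B,Ho,Wo,Cout)
        y = y.transpose(0, 3, 1, 2)
    else:
        co_g = cout // groups
        y = np.empty((b, cout, ho, wo), dtype=x.data.dtype)
        cols = []
        for gix in range(groups):
            xg = xp[:, gix * cin_g:(gix + 1) * cin_g]
            cg = _im2col(xg, kh, kw)
            cols.append(cg)
            wm = w.data[gix * co_g:(gix + 1) * co_g].reshape(co_g, -1)
            y[:, gix * co_g:(gix + 1) * co_g] = (cg @ wm.T).transpose(0, 3, 1, 2)
    out = Tensor(y, x.requires_grad or w.requires_grad, (x, w))

    def bw(g):
        # g: (B, Cout, Ho, Wo)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            if groups == 1:
                gm = g.transpose(0, 2, 3, 1).reshape(-1, cout)       # (BHoWo,Cout)
                c = cols.reshape(-1, cin_g * kh * kw)
                gw[:] = (gm.T @ c).reshape(w.data.shape)
            else:
                co_g2 = cout // groups
                for gix in range(groups):
                    gm = g[:, gix * co_g2:(gix + 1) * co_g2].transpose(
                        0, 2, 3, 1).reshape(-1, co_g2)
                    c = cols[gix].reshape(-1, cin_g * kh * kw)
                    gw[gix * co_g2:(gix + 1) * co_g2] = (gm.T @ c).reshape(
                        co_g2, cin_g, kh, kw)
            w._accum(gw)
        if x.requires_grad:
            # transposed convolution: pad grad by (k-1), correlate with
            # spatially flipped kernels, swapping in/out channels per group.
            gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
            wf = w.data[:, :, ::-1, ::-1]
            gx_full = np.empty((b, cin, h + pt + pb, wdt + pl + pr),
                               dtype=x.data.dtype)
            co_g2 = cout // groups
            for gix in range(groups):
                gpg = gp[:, gix * co_g2:(gix + 1) * co_g2]
                # kernel for transpose: (Cin_g, Cout_g, kh, kw)
                wt = wf[gix * co_g2:(gix + 1) * co_g2].transpose(1, 0, 2, 3)
                cg = _im2col(gpg, kh, kw)                 # (B,H',W',Cout_g*kh*kw)
                wm = wt.reshape(cin_g, -1)
                gx = (cg @ wm.T).transpose(0, 3, 1, 2)
                gx_full[:, gix * cin_g:(gix + 1) * cin_g] = gx
            gx_full = gx_full[:, :, pt:pt + h, pl:pl + wdt]
            x._accum(gx_full)

    out._backward = bw
    return out


def avg_pool_w(x: Tensor, p: int) -> Tensor:
    """Average pooling along the last axis, window = stride = ``p`` (floor)."""
    b, c, h, wdt = x.data.shape
    wo = wdt // p
    xt = x.data[..., : wo * p].reshape(b, c, h, wo, p)
    out = Tensor(xt.mean(axis=-1), x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[..., : wo * p] = np.repeat(g / p, p, axis=-1)
            x._accum(gx)

    out._backward = bw
    return out
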