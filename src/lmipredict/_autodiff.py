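"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine is deliberately small: dense tensors, a static tape built on the
fly, and exactly the operations the model needs (broadcasted arithmetic,
batched matmul, reductions, softmax, sigmoid/ReLU/SiLU, log/exp, clipping,
concatenation, gather).  Gradients follow the usual vector-Jacobian-product
rules; broadcasting is undone by summing over the broadcast axes.

Dtypes are preserved: float32 graphs stay float32 (training), float64 graphs
stay float64 (gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "as_tensor", "concat", "stack", "glorot"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    def detach(self):
        return Tensor(self.data)

    def item(self):
        return float(self.data.item())

    def backward(self):
        """Reverse-mode sweep from this (scalar or any-shape) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        g = np.asarray(g, dtype=self.data.dtype)
        if self.grad is None:
            # no copy: grads are never mutated in place, only rebound via `+`
            self.grad = g
        else:
            self.grad = self.grad + g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other, like=self)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data + other.data, out_req, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw if out_req else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other, like=self))

    def __rsub__(self, other):
        return as_tensor(other, like=self) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, like=self)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data * other.data, out_req, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw if out_req else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, like=self)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other, like=self)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data @ other.data, out_req, (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw if out_req else None
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(np.swapaxes(g, a, b))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def take(self, indices, axis=0):
        """Gather rows (embedding lookup)."""
        indices = np.asarray(indices)
        out = Tensor(np.take(self.data, indices, axis=axis), self.requires_grad, (self,))
        if self.requires_grad:

            def bw(g):
                acc = np.zeros_like(self.data)
                np.add.at(acc, (slice(None),) * axis + (indices,), g)
                self._accum(acc)

            out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        if self.requires_grad:

            def bw(g):
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accum(acc)

            out._backward = bw
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))
        if self.requires_grad:

            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape))

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------ nonlinearity
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def relu(self):
        y = np.maximum(self.data, 0)
        out = Tensor(y, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g * y * (1 - y))
        return out

    def silu(self):
        """x * sigmoid(x) with a fused backward."""
        s = 1.0 / (1.0 + np.exp(-self.data))
        y = self.data * s
        out = Tensor(y, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g * (s + y * (1 - s)))
        return out

    def softmax(self, axis=-1):
        """Numerically stable softmax along `axis`."""
        y = self.data - self.data.max(axis=axis, keepdims=True)
        np.exp(y, out=y)
        y /= y.sum(axis=axis, keepdims=True)
        out = Tensor(y, self.requires_grad, (self,))
        if self.requires_grad:

            def bw(g):
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))

            out._backward = bw
        return out

    def clip(self, lo, hi):
        y = np.clip(self.data, lo, hi)
        out = Tensor(y, self.requires_grad, (self,))
        if self.requires_grad:
            mask = (self.data > lo) & (self.data < hi)
            out._backward = lambda g: self._accum(g * mask)
        return out

    # ----------------------------------------------------------- compositions
    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Row-wise layer normalization over the last axis with affine params.

        Fused forward/backward: for xhat = (x - mu)/sigma,
        dx = (g*gamma - mean(g*gamma) - xhat * mean(g*gamma*xhat)) / sigma.
        """
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out_req = self.requires_grad or gamma.requires_grad or beta.requires_grad
        out = Tensor(xhat * gamma.data + beta.data, out_req, (self, gamma, beta))

        def bw(g):
            if gamma.requires_grad:
                gamma._accum(_unbroadcast(g * xhat, gamma.shape))
            if beta.requires_grad:
                beta._accum(_unbroadcast(g, beta.shape))
            if self.requires_grad:
                gg = g * gamma.data
                m1 = gg.mean(axis=-1, keepdims=True)
                m2 = (gg * xhat).mean(axis=-1, keepdims=True)
                self._accum((gg - m1 - xhat * m2) * inv)

        out._backward = bw if out_req else None
        return out

    def l2_normalize(self, eps: float = 1e-12):
        nrm = ((self * self).sum(axis=-1, keepdims=True) + eps) ** 0.5
        return self / nrm

    def logsumexp(self, axis=-1):
        """Stable log-sum-exp (the shift is a constant w.r.t. the graph)."""
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self - Tensor(m)
        lse = shifted.exp().sum(axis=axis).log()
        return lse + Tensor(np.squeeze(m, axis=axis))


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.dtype if like is not None and np.isscalar(x) else None
    return Tensor(np.asarray(x, dtype=dtype))


def concat(tensors, axis=0) -> Tensor:
    tensors = list(tensors)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), req, tuple(tensors))
    if req:
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])

        out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = list(tensors)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), req, tuple(tensors))
    if req:

        def bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis))

        out._backward = bw
    return out


def glorot(rng: np.random.Generator, shape, dtype=np.float32) -> Tensor:
    """Glorot/Xavier-uniform initialized parameter tensor."""
    fan_in, fan_out = (shape[-2], shape[-1]) if len(shape) >= 2 else (shape[0], shape[0])
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=shape).astype(dtype), requires_grad=True)


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
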