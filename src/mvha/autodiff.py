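"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the hybrid attentive model needs:
broadcast-aware elementwise arithmetic, matmul, the sigmoid/tanh/ReLU
nonlinearities, softmax building blocks (exp/log/sum/max-shift), tensor
reshaping/stacking/slicing, 1-D convolution, non-overlapping max pooling,
dropout and batch normalization, plus an Adam optimizer.

Gradients are accumulated by topological traversal of the recorded graph.
The 1-D convolution avoids materializing an im2col buffer by looping over
the (small) kernel taps, so memory stays proportional to the activations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "conv1d", "maxpool1d", "dropout",
           "softmax", "batchnorm", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; graphs from unrolled LSTMs get deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g) if self.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = _bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data
        out = Tensor(a @ b, _parents=(self, other))

        def _bwd(g):
            if a.ndim >= 2 and b.ndim >= 2:
                if self.requires_grad:
                    self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))
            elif b.ndim == 1 and a.ndim >= 2:
                # out[..., m] = sum_n a[..., m, n] b[n]
                if self.requires_grad:
                    self._accum(g[..., None] * b)
                if other.requires_grad:
                    other._accum(np.einsum("...mn,...m->n", a, g, optimize=True))
            elif a.ndim == 1 and b.ndim >= 2:
                # out[..., n] = sum_m a[m] b[..., m, n]
                if self.requires_grad:
                    self._accum(np.einsum("...n,...mn->m", g, b, optimize=True))
                if other.requires_grad:
                    other._accum(_unbroadcast(a[:, None] * g[..., None, :], b.shape))
            else:  # both 1-D: inner product
                if self.requires_grad:
                    self._accum(g * b)
                if other.requires_grad:
                    other._accum(g * a)

        out._backward = _bwd
        return out

    # ---------------------------------------------------------- nonlinearities
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data) if self.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data) if self.requires_grad else None
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data ** 2)) if self.requires_grad else None
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s)) if self.requires_grad else None
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        mask = self.data > 0
        out._backward = lambda g: self._accum(g * mask) if self.requires_grad else None
        return out

    def clamp_min(self, lo: float):
        out = Tensor(np.maximum(self.data, lo), _parents=(self,))
        mask = self.data > lo
        out._backward = lambda g: self._accum(g * mask) if self.requires_grad else None
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def _bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- structural
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape)) if self.requires_grad else None
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv)) if self.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def _bwd(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, idx, g)
                self._accum(gx)

        out._backward = _bwd
        return out


# ----------------------------------------------------------------- free ops

def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = _bwd
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def _bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = _bwd
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """Valid-mode 1-D convolution (cross-correlation).

    x: (B, C, n); w: (U, C, K); b: (U,) -> out (B, U, J), J = (n-K)//stride + 1.
    Implemented as a loop over the K kernel taps to keep memory at O(B*C*J).
    """
    B, C, n = x.data.shape
    U, Cw, K = w.data.shape
    if Cw != C:
        raise ValueError(f"conv1d channel mismatch: input has {C}, kernel expects {Cw}")
    if n < K:
        raise ValueError(f"conv1d input length {n} shorter than kernel {K}")
    J = (n - K) // stride + 1
    out_data = np.zeros((B, U, J))
    for k in range(K):
        xs = x.data[:, :, k : k + (J - 1) * stride + 1 : stride]      # (B, C, J)
        out_data += np.einsum("uc,bcj->buj", w.data[:, :, k], xs, optimize=True)
    if b is not None:
        out_data += b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def _bwd(g):
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for k in range(K):
                xs = x.data[:, :, k : k + (J - 1) * stride + 1 : stride]
                gw[:, :, k] = np.einsum("buj,bcj->uc", g, xs, optimize=True)
            w._accum(gw)
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for k in range(K):
                gx[:, :, k : k + (J - 1) * stride + 1 : stride] += np.einsum(
                    "buj,uc->bcj", g, w.data[:, :, k], optimize=True)
            x._accum(gx)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))

    out._backward = _bwd
    return out


def maxpool1d(x: Tensor, width: int) -> Tensor:
    """Non-overlapping max pooling over the last axis; trailing remainder dropped."""
    B, U, n = x.data.shape
    J = n // width
    if J == 0:
        raise ValueError(f"maxpool1d: length {n} shorter than pool width {width}")
    xv = x.data[:, :, : J * width].reshape(B, U, J, width)
    arg = xv.argmax(axis=3)
    out = Tensor(xv.max(axis=3), _parents=(x,))

    def _bwd(g):
        if not x.requires_grad:
            return
        gx = np.zeros((B, U, J, width))
        np.put_along_axis(gx, arg[..., None], g[..., None], axis=3)
        full = np.zeros_like(x.data)
        full[:, :, : J * width] = gx.reshape(B, U, J * width)
        x._accum(full)

    out._backward = _bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax: the max shift is a constant w.r.t. the graph."""
    shift = x.data.max(axis=axis, keepdims=True)
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
              training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over all axes except axis 1 (the feature axis).

    Implemented as a single primitive with the standard analytic backward
    pass (keeps memory at two activation-sized buffers).  `running` holds
    'mean' and 'var' arrays of shape (C,), updated in place during training
    and used verbatim at evaluation time.
    """
    axes = tuple(i for i in range(x.ndim) if i != 1)
    shape = [1] * x.ndim
    shape[1] = x.data.shape[1]
    if training:
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        if not running.get("initialized", False):
            # warm-start from the first batch: raw physiological inputs sit far
            # from the (0, 1) cold start, which otherwise poisons eval passes
            running["mean"] = mu.reshape(-1).copy()
            running["var"] = var.reshape(-1).copy()
            running["initialized"] = True
        else:
            running["mean"] = (1 - momentum) * running["mean"] + momentum * mu.reshape(-1)
            running["var"] = (1 - momentum) * running["var"] + momentum * var.reshape(-1)
    else:
        mu = running["mean"].reshape(shape)
        var = running["var"].reshape(shape)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(gamma.data.reshape(shape) * xhat + beta.data.reshape(shape),
                 _parents=(x, gamma, beta))

    def _bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(shape)
            if training:
                x._accum(inv * (gxhat - gxhat.mean(axis=axes, keepdims=True)
                                - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)))
            else:
                x._accum(gxhat * inv)

    out._backward = _bwd
    return out


class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, params: list[Tensor], lr: float = 0.002):
        self.params = list(params)
        self.lr = lr

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adagrad:
    """Adagrad with accumulated squared gradients."""

    def __init__(self, params: list[Tensor], lr: float = 0.002, eps: float = 1e-10):
        self.params = list(params)
        self.lr = lr
        self.eps = eps
        self.acc = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.acc[i] += p.grad * p.grad
            p.data -= self.lr * p.grad / (np.sqrt(self.acc[i]) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 0.002,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
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

    def zero_grad(self):
        for p in self.params:
            p.grad = None
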