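"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains small fused language+graph models; the layer math (matrix
products, softmax, LeakyReLU scoring, layer norm) is expressed with the
:class:`Tensor` class below, which records a computation graph and backpropagates
gradients with ``backward()``. Only the operations the model architectures need
are implemented. Arrays keep whatever float dtype they are given (training uses
float32, oracle checks float64).
"""

from __future__ import annotations

import numpy as np

from .exceptions import ShapeError

__all__ = ["Tensor", "Parameter", "Module", "Linear", "LayerNorm", "Adam",
           "cat", "dropout", "softmax_lastdim"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=grad.dtype)
        self.grad = self.grad + grad

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)

        def backward(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._make(a.data ** p, (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)
        if a.data.shape[-1] != b.data.shape[-2 if b.data.ndim > 1 else 0]:
            raise ShapeError(
                f"matmul shapes incompatible: {a.shape} @ {b.shape}")

        def backward(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def leaky_relu(self, negative_slope: float = 0.2):
        a = self
        factor = np.where(a.data > 0, 1.0, negative_slope)

        def backward(g):
            if a.requires_grad:
                a._accum(g * factor)

        return Tensor._make(a.data * factor, (a,), backward)

    def clip(self, lo: float, hi: float):
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), backward)

    # -- reductions and reshaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                g_exp = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g_exp, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims),
                            (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(a.shape))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        axes = axes or None

        def backward(g):
            if a.requires_grad:
                if axes is None:
                    a._accum(g.T)
                else:
                    a._accum(np.transpose(g, np.argsort(axes)))

        return Tensor._make(np.transpose(a.data, axes), (a,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(np.swapaxes(g, ax1, ax2))

        return Tensor._make(np.swapaxes(a.data, ax1, ax2), (a,), backward)

    def __getitem__(self, idx):
        a = self
        if isinstance(idx, (list, np.ndarray)):
            idx = np.asarray(idx)

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data, dtype=g.dtype)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._make(a.data[idx], (a,), backward)

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def cat(tensors, axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient support."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def softmax_lastdim(x: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax over the last axis.

    ``additive_mask`` (a constant array, e.g. -1e9 at disallowed positions) is
    added to the logits before normalization.
    """
    if additive_mask is not None:
        x = x + Tensor(additive_mask)
    shifted = x - Tensor(x.data.max(axis=-1, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=-1, keepdims=True)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout: active only in training mode."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(mask)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Lightweight container for parameters and submodules."""

    def __init__(self):
        self.training = True

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{path}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{path}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self.training = True
        for child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for child in self._children():
            child.eval()
        return self

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ShapeError(
                    f"parameter {name}: shape {p.data.shape} vs "
                    f"checkpoint {state[name].shape}")
            p.data = state[name].astype(p.data.dtype, copy=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float32):
        super().__init__()
        self.W = Parameter(_glorot(rng, d_in, d_out, (d_in, d_out), dtype))
        self.b = Parameter(np.zeros(d_out, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    __call__ = forward


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(d, dtype=dtype))
        self.beta = Parameter(np.zeros(d, dtype=dtype))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.gamma + self.beta

    __call__ = forward


class Adam:
    """Adam with parameter groups (distinct base learning rates).

    ``groups`` is a list of dicts ``{"params": [...], "lr": float}``. The
    training loop rescales ``lr`` per epoch according to the warmup /
    inverse-square-root schedule before calling :meth:`step`.
    """

    def __init__(self, groups, betas=(0.9, 0.999), eps: float = 1e-8):
        self.groups = [dict(g) for g in groups]
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for group in self.groups:
            lr = group["lr"]
            for p in group["params"]:
                if not p.requires_grad or p.grad is None:
                    continue
                g = p.grad.astype(p.data.dtype, copy=False)
                key = id(p)
                if key not in self._m:
                    self._m[key] = np.zeros_like(p.data)
                    self._v[key] = np.zeros_like(p.data)
                self._m[key] = b1 * self._m[key] + (1 - b1) * g
                self._v[key] = b2 * self._v[key] + (1 - b2) * g * g
                m_hat = self._m[key] / (1 - b1 ** self.t)
                v_hat = self._v[key] / (1 - b2 ** self.t)
                p.data = p.data - lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for group in self.groups:
            for p in group["params"]:
                p.grad = None
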