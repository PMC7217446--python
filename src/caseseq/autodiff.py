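"""A small reverse-mode automatic differentiation engine over numpy arrays.

Supports exactly the operations the package's neural components need:
broadcast-aware arithmetic, (batched) matrix multiplication, pointwise
nonlinearities, reductions including a numerically stable log-sum-exp,
concatenation/reshaping, and gather-style indexing with scatter-add
gradients (used for embedding lookups). Gradients are accumulated by a
topological-order backward pass from a scalar loss.

All computation is float64 numpy; determinism follows from numpy's.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[Array], Sequence[Array | None]] | None = None,
        name: str | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward
        self.name = name

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def backward(self) -> None:
        """Backpropagate from this scalar."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += pgrad

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g, self.shape),
                _unbroadcast(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, _parents=(self,), _backward=lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.data / other.data,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __pow__(self, exponent: float) -> "Tensor":
        out = self.data**exponent
        return Tensor(
            out,
            _parents=(self,),
            _backward=lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g: Array):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=backward)

    # -- pointwise nonlinearities ----------------------------------------

    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor(out, _parents=(self,), _backward=lambda g: (g * out,))

    def log(self) -> "Tensor":
        return Tensor(
            np.log(self.data), _parents=(self,), _backward=lambda g: (g / self.data,)
        )

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)
        return Tensor(out, _parents=(self,), _backward=lambda g: (g * (1 - out**2),))

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, _parents=(self,), _backward=lambda g: (g * out * (1 - out),))

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor(
            np.where(mask, self.data, 0.0),
            _parents=(self,),
            _backward=lambda g: (g * mask,),
        )

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        out = np.where(pos, self.data, alpha * (np.exp(np.minimum(self.data, 0.0)) - 1))
        return Tensor(
            out,
            _parents=(self,),
            _backward=lambda g: (g * np.where(pos, 1.0, out + alpha),),
        )

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: Array):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor(out, _parents=(self,), _backward=backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient flows to the first argmax (ties)."""
        out = self.data.max(axis=axis, keepdims=keepdims)
        idx = self.data.argmax(axis=axis)
        onehot = np.zeros_like(self.data)
        np.put_along_axis(onehot, np.expand_dims(idx, axis), 1.0, axis=axis)

        def backward(g: Array):
            gg = g if keepdims else np.expand_dims(g, axis)
            return (onehot * gg,)

        return Tensor(out, _parents=(self,), _backward=backward)

    def logsumexp(self, axis: int = -1, keepdims: bool = False) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        out = m + np.log(s)
        soft = e / s

        def backward(g: Array):
            gg = g if keepdims else np.expand_dims(g, axis)
            return (soft * gg,)

        return Tensor(
            out if keepdims else np.squeeze(out, axis=axis),
            _parents=(self,),
            _backward=backward,
        )

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(
            self.data.reshape(shape),
            _parents=(self,),
            _backward=lambda g: (g.reshape(self.shape),),
        )

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            _parents=(self,),
            _backward=lambda g: (g.transpose(inverse),),
        )

    def swapaxes(self, a: int, b: int) -> "Tensor":
        return Tensor(
            np.swapaxes(self.data, a, b),
            _parents=(self,),
            _backward=lambda g: (np.swapaxes(g, a, b),),
        )

    def __getitem__(self, index) -> "Tensor":
        def backward(g: Array):
            out = np.zeros_like(self.data)
            np.add.at(out, index, g)
            return (out,)

        return Tensor(self.data[index], _parents=(self,), _backward=backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def parameter(data, name: str | None = None) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True, name=name)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: Array):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=backward,
    )


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def backward(g: Array):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=backward,
    )


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Row-stochastic softmax; stable via detached max subtraction.

    Entries equal to -inf receive exactly zero weight, which keeps masked
    attention bitwise independent of masked-out values.
    """
    shifted = t - Tensor(
        np.where(
            np.isfinite(t.data.max(axis=axis, keepdims=True)),
            t.data.max(axis=axis, keepdims=True),
            0.0,
        )
    )
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    return t - t.logsumexp(axis=axis, keepdims=True)


def collect_parameters(*objects) -> list[Tensor]:
    """Gather unique trainable tensors from objects exposing .parameters()."""
    params: list[Tensor] = []
    seen: set[int] = set()
    for obj in objects:
        if obj is None:
            continue
        for p in obj.parameters():
            if id(p) not in seen:
                seen.add(id(p))
                params.append(p)
    return params


class Adam:
    """Adam optimizer with the common default moment coefficients."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self._m[i] = b1 * self._m[i] + (1 - b1) * p.grad
            self._v[i] = b2 * self._v[i] + (1 - b2) * p.grad**2
            mhat = self._m[i] / (1 - b1**self.t)
            vhat = self._v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))
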