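"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is a deliberately small tensor engine: dense arrays, a handful of
operators (enough for graph-convolutional autoencoders with masked
attention softmax and a Student-t clustering head), and an Adam
optimizer. Broadcasting follows NumPy semantics; gradients of broadcast
operands are summed back to the operand's shape.

Everything is float64 by default; callers may pass float32 arrays for
speed, the engine preserves dtype.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- operators
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = fwd(self.data, other.data)
        req = self.requires_grad or other.requires_grad

        def backward(g: np.ndarray) -> None:
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))

        return Tensor(out_data, req, (self, other), backward)

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor._lift(other) - self

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __neg__(self):
        return self * (-1.0)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data @ other.data
        req = self.requires_grad or other.requires_grad

        def backward(g: np.ndarray) -> None:
            if self.requires_grad or self._parents:
                self._accum(g @ other.data.T)
            if other.requires_grad or other._parents:
                other._accum(self.data.T @ g)

        return Tensor(out_data, req, (self, other), backward)

    def powc(self, p: float) -> "Tensor":
        """Elementwise power with a constant exponent."""
        out_data = self.data ** p

        def backward(g: np.ndarray) -> None:
            self._accum(g * p * self.data ** (p - 1.0))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            self._accum(g * out_data)

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g: np.ndarray) -> None:
            self._accum(g / self.data)

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0)

        def backward(g: np.ndarray) -> None:
            self._accum(g * (self.data > 0))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g: np.ndarray) -> None:
            self._accum(g * (1.0 - out_data * out_data))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g: np.ndarray) -> None:
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(out_data, self.requires_grad, (self,), backward)

    @property
    def T(self) -> "Tensor":
        out_data = self.data.T

        def backward(g: np.ndarray) -> None:
            self._accum(g.T)

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def sqnorm(self) -> "Tensor":
        """Squared Frobenius norm, as a scalar tensor."""
        return (self * self).sum()


def masked_softmax_attention(s: Tensor, r: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise attention coefficients from per-node scores.

    Computes ``U = sigmoid(s_i + r_j)`` on the nonzero pattern of `mask`
    and returns the row-softmax of U restricted to that pattern. `s` and
    `r` are (n, 1) tensors of per-node source/neighbour scores; `mask` is
    a constant 0/1 array (typically the adjacency with self-loops). Rows
    with an empty mask fall back to a unit self-loop.

    Implemented as one fused operator for speed: the composed elementwise
    chain dominates training cost on dense masks otherwise.
    """
    m = np.asarray(mask)
    S = s.data + r.data.T            # (n, n) pre-activation
    U = 1.0 / (1.0 + np.exp(-S))
    E = np.exp(U) * m
    row = E.sum(axis=1, keepdims=True)
    empty = row[:, 0] == 0
    Y = np.divide(E, row, out=np.zeros_like(E), where=row > 0)
    if empty.any():
        Y[empty, empty] = 1.0

    def backward(g: np.ndarray) -> None:
        # softmax backward on the masked pattern
        dU = Y * (g - (g * Y).sum(axis=1, keepdims=True))
        dS = dU * U * (1.0 - U) * m
        if s.requires_grad or s._parents:
            s._accum(dS.sum(axis=1, keepdims=True))
        if r.requires_grad or r._parents:
            r._accum(dS.sum(axis=0, keepdims=True).T)

    return Tensor(Y, s.requires_grad or r.requires_grad, (s, r), backward)


def constant(x: np.ndarray) -> Tensor:
    return Tensor(np.asarray(x), requires_grad=False)


def parameter(x: np.ndarray) -> Tensor:
    return Tensor(np.asarray(x, dtype=float), requires_grad=True)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
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
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
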