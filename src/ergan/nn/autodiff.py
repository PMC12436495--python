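"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package (a bidirectional-LSTM GAN and two transformer
classifiers) are small enough to train on a CPU, so they are built on this
compact tape-based autodiff core rather than a heavyweight framework.  All
arithmetic is float64 numpy, which keeps training bit-reproducible for a
fixed seed on a fixed BLAS.

Only the operations the models need are implemented.  Sequence recurrences
(LSTM) are fused into a single primitive with a hand-written
backward-through-time pass so the graph holds one node per layer call
instead of one per timestep.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "leaky_relu",
    "log",
    "lstm",
    "matmul",
    "relu",
    "sigmoid",
    "softmax",
    "tanh",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, parents=(), vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._vjp = vjp

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._vjp(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                pgrad = _unbroadcast(np.asarray(pgrad), parent.data.shape)
                if parent.grad is None:
                    parent.grad = pgrad
                else:
                    parent.grad = parent.grad + pgrad

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
            lambda g: (g, g),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, self.requires_grad, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        return Tensor(
            a.data * b.data,
            a.requires_grad or b.requires_grad,
            (a, b),
            lambda g: (g * b.data, g * a.data),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        return Tensor(
            a.data / b.data,
            a.requires_grad or b.requires_grad,
            (a, b),
            lambda g: (g / b.data, -g * a.data / (b.data**2)),
        )

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __pow__(self, p: float):
        a = self
        return Tensor(
            a.data**p,
            a.requires_grad,
            (a,),
            lambda g: (g * p * a.data ** (p - 1),),
        )

    def __getitem__(self, idx):
        a = self

        def vjp(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(a.data[idx], a.requires_grad, (a,), vjp)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(
            a.data.reshape(shape),
            a.requires_grad,
            (a,),
            lambda g: (g.reshape(a.data.shape),),
        )

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return Tensor(
            a.data.swapaxes(ax1, ax2),
            a.requires_grad,
            (a,),
            lambda g: (g.swapaxes(ax1, ax2),),
        )

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.data.shape).copy(),)

        return Tensor(a.data.sum(axis=axis, keepdims=keepdims), a.requires_grad, (a,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities ---------------------------------------------

def exp(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)
    return Tensor(out_data, a.requires_grad, (a,), lambda g: (g * out_data,))


def log(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    return Tensor(np.log(a.data), a.requires_grad, (a,), lambda g: (g / a.data,))


def tanh(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    t = np.tanh(a.data)
    return Tensor(t, a.requires_grad, (a,), lambda g: (g * (1.0 - t * t),))


def sigmoid(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    s = _sigmoid(a.data)
    return Tensor(s, a.requires_grad, (a,), lambda g: (g * s * (1.0 - s),))


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    mask = np.where(a.data > 0.0, 1.0, slope)
    return Tensor(a.data * mask, a.requires_grad, (a,), lambda g: (g * mask,))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# -- linear algebra ----------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        ga = g @ b.data.swapaxes(-1, -2)
        gb = a.data.swapaxes(-1, -2) @ g
        return ga, gb

    return Tensor(a.data @ b.data, a.requires_grad or b.requires_grad, (a, b), vjp)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
        vjp,
    )


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    s = ez / ez.sum(axis=axis, keepdims=True)

    def vjp(g):
        gs = g * s
        return (gs - s * gs.sum(axis=axis, keepdims=True),)

    return Tensor(s, a.requires_grad, (a,), vjp)


# -- fused LSTM primitive -----------------------------------------------------

def lstm(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor, reverse: bool = False) -> Tensor:
    """One LSTM pass over a (batch, time, features) sequence.

    Gate order in the packed weight matrices is input, forget, cell, output.
    Initial hidden and cell states are zero.  ``reverse=True`` runs the
    recurrence from the last timestep to the first (the output stays aligned
    with the input time axis), which is how the bidirectional layer reuses
    this primitive.

    The whole recurrence is one graph node: the forward pass caches the gate
    activations and the backward pass replays them in reverse
    (backpropagation through time).
    """
    from ._lstm_kernels import lstm_backward, lstm_forward

    x, wx, wh, b = map(_as_tensor, (x, wx, wh, b))

    # input contribution for every step at once, then the compiled recurrence
    xw = x.data @ wx.data + b.data  # (B, T, 4H)
    caches = lstm_forward(np.ascontiguousarray(xw), wh.data, reverse)
    h_seq = caches[-1]

    def vjp(grad_h: np.ndarray):
        return lstm_backward(
            np.ascontiguousarray(grad_h),
            x.data,
            wx.data,
            wh.data,
            *caches[:-1],
            h_seq,
            reverse,
        )

    req = any(t.requires_grad for t in (x, wx, wh, b))
    return Tensor(h_seq, req, (x, wx, wh, b), vjp)
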