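"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package trains its sequence model with plain NumPy; this module supplies
the differentiable :class:`Tensor` plus the handful of primitives the model
needs (broadcast arithmetic, matmul, activations, softmax, concat/stack,
slicing, reductions, and a fused LSTM layer with a hand-written
backward-through-time pass).  Gradients are accumulated in ``float64``.

Only the operations actually used by the model are implemented; this is not a
general-purpose framework.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack", "lstm", "relu", "sigmoid", "tanh", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
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
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- bookkeeping ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack_.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = _bw
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = _bw
        return out

    # -- shape ops ------------------------------------------------------

    def reshape(self, shape: tuple[int, ...]) -> "Tensor":
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = _bw
        return out

    def broadcast_to(self, shape: tuple[int, ...]) -> "Tensor":
        out = Tensor(np.broadcast_to(self.data, shape).copy(), _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))

        out._backward = _bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                np.add.at(buf, idx, g)
                self._accumulate(buf)

        out._backward = _bw
        return out

    # -- reductions -----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities ------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        s = _expit(self.data)
        out = Tensor(s, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = _bw
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (1.0 - t * t))

        out._backward = _bw
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * e)

        out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = _bw
        return out

    def clip_min(self, floor: float) -> "Tensor":
        """max(self, floor); gradient passes only where self > floor."""
        out = Tensor(np.maximum(self.data, floor), _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (self.data > floor))

        out._backward = _bw
        return out


def _expit(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def tanh(x: Tensor) -> Tensor:
    return x.tanh()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # Shifting by the (detached) max leaves both value and gradient unchanged.
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g: np.ndarray) -> None:
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = _bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))

    def _bw(g: np.ndarray) -> None:
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece.squeeze(axis))

    out._backward = _bw
    return out


def lstm(x: Tensor, w_ih: Tensor, w_hh: Tensor, b: Tensor) -> Tensor:
    """One LSTM layer over a batched sequence, fused for speed.

    Parameters
    ----------
    x : (B, S, n_in)
    w_ih : (n_in, 4*n_h) input weights, gate order (input, forget, cell, output)
    w_hh : (n_h, 4*n_h) recurrent weights
    b : (4*n_h,) bias

    Returns (B, S, n_h) hidden states.  Initial hidden and cell states are
    zero.  The backward pass is a hand-written backprop-through-time loop so
    that a full sequence contributes a single node to the autodiff graph.
    """
    B, S, _ = x.shape
    H = w_hh.shape[0]
    xd, wi, wh, bd = x.data, w_ih.data, w_hh.data, b.data

    h_prev = np.zeros((B, H))
    c_prev = np.zeros((B, H))
    # caches for BPTT
    I = np.empty((S, B, H)); F = np.empty((S, B, H))
    Gc = np.empty((S, B, H)); O = np.empty((S, B, H))
    C = np.empty((S, B, H)); Tc = np.empty((S, B, H))
    Hs = np.empty((S, B, H))
    x_wi = xd @ wi  # (B, S, 4H), one big matmul up front
    for t in range(S):
        z = x_wi[:, t, :] + h_prev @ wh + bd
        i = _expit(z[:, :H]); f = _expit(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H]); o = _expit(z[:, 3 * H:])
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        I[t], F[t], Gc[t], O[t], C[t], Tc[t], Hs[t] = i, f, g, o, c, tc, h
        h_prev, c_prev = h, c

    out = Tensor(np.transpose(Hs, (1, 0, 2)), _parents=(x, w_ih, w_hh, b))

    def _bw(grad: np.ndarray) -> None:
        dh_out = np.transpose(grad, (1, 0, 2))  # (S, B, H)
        dwi = np.zeros_like(wi); dwh = np.zeros_like(wh); db = np.zeros_like(bd)
        dx = np.zeros_like(xd)
        dh_next = np.zeros((B, H)); dc_next = np.zeros((B, H))
        for t in range(S - 1, -1, -1):
            dh = dh_out[t] + dh_next
            i, f, g, o, tc = I[t], F[t], Gc[t], O[t], Tc[t]
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * (C[t - 1] if t > 0 else np.zeros((B, H)))
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)  # (B, 4H)
            dx[:, t, :] = dz @ wi.T
            h_before = Hs[t - 1] if t > 0 else np.zeros((B, H))
            dwi += xd[:, t, :].T @ dz
            dwh += h_before.T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ wh.T
            dc_next = dc * f
        if x.requires_grad:
            x._accumulate(dx)
        if w_ih.requires_grad:
            w_ih._accumulate(dwi)
        if w_hh.requires_grad:
            w_hh._accumulate(dwh)
        if b.requires_grad:
            b._accumulate(db)

    out._backward = _bw
    return out
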