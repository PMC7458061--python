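"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the classifier needs: broadcasting
elementwise arithmetic, (batched) matrix products, the usual activations,
softmax/log-softmax, reductions, concatenation, slicing and gathering
along the time axis.  Gradients flow only into :class:`Tensor` leaves with
``requires_grad=True``; plain numpy arrays entering an op are treated as
constants.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "concat", "stack", "matmul",
           "take_along_time", "softmax", "log_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        """Accumulate a gradient; ``own=True`` promises ``grad`` is a fresh
        array no other tensor aliases, so it can be adopted without a copy."""
        if self.grad is None:
            self.grad = grad if own else grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ---------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(-g, own=True)
        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape), own=True)
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.data.shape), own=True)
        out._backward = backward
        return out

    # -- matmul --------------------------------------------------------------
    def __matmul__(self, other):
        return matmul(self, other)

    # -- activations ---------------------------------------------------------
    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y), own=True)
        out._backward = backward
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y), own=True)
        out._backward = backward
        return out

    def relu(self):
        y = np.maximum(self.data, 0.0)
        out = Tensor(y, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0.0), own=True)
        out._backward = backward
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * y, own=True)
        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data, own=True)
        out._backward = backward
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy(), own=True)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy(), own=True)
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        count = (self.data.size if axis is None else self.data.shape[axis])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims=False):
        """Max reduction; gradient flows to the first argmax per slice."""
        idx = np.expand_dims(self.data.argmax(axis=axis), axis)
        y = np.take_along_axis(self.data, idx, axis=axis)
        out_data = y if keepdims else np.squeeze(y, axis=axis)
        out = Tensor(out_data, (self,))

        def backward(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, idx, g, axis=axis)
            self._accum(full, own=True)
        out._backward = backward
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = backward
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), (self,))
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(*inverse))
        out._backward = backward
        return out

    def swap_last(self):
        """Swap the last two axes (transpose for batched matrices)."""
        out = Tensor(np.swapaxes(self.data, -1, -2), (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, -1, -2))
        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], (self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)
        out._backward = backward
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def constant(x) -> Tensor:
    return _as_tensor(x)


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)


def matmul(a: Tensor, b) -> Tensor:
    a = _as_tensor(a)
    b = _as_tensor(b)
    out = Tensor(np.matmul(a.data, b.data), (a, b))

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.data.shape), own=True)
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.data.shape), own=True)
    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)
    out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

    def backward(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis))
    out._backward = backward
    return out


def take_along_time(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather along axis 1 of a (B, T, D) tensor with per-sequence indices
    ``idx`` of shape (B, T); backward scatter-adds."""
    idx3 = idx[:, :, None]
    out = Tensor(np.take_along_axis(t.data, np.broadcast_to(
        idx3, t.data.shape), axis=1), (t,))

    def backward(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            np.put_along_axis(full, np.broadcast_to(idx3, t.data.shape),
                              g, axis=1)  # indices are a permutation per row
            t._accum(full)
    out._backward = backward
    return out


def unstack_time(t: Tensor) -> list[Tensor]:
    """Split a (B, T, D) tensor into T views of shape (B, D).

    Each child's backward writes straight into a slice of the parent's
    gradient buffer, avoiding one full-size allocation per timestep.
    """
    _, T, _ = t.data.shape

    def make_backward(i):
        def backward(g):
            if t.requires_grad:
                if t.grad is None:
                    t.grad = np.zeros_like(t.data)
                t.grad[:, i] += g
        return backward

    outs = []
    for i in range(T):
        out = Tensor(t.data[:, i], (t,))
        out._backward = make_backward(i)
        outs.append(out)
    return outs


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t + constant(-t.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t + constant(-t.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
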