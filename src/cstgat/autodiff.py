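"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network here is small (one graph-attention layer, a BiLSTM, a linear
classifier), so a compact tape-based autodiff is sufficient and keeps every
forward computation an explicit, inspectable numpy expression in float64 —
which is also what makes finite-difference gradient checks meaningful.

Only the primitives the model needs are implemented: elementwise arithmetic
with numpy broadcasting, matmul (batched), the gate nonlinearities, masked
softmax building blocks, reductions, reshapes and concatenation, plus a
fused softmax cross-entropy loss and an Adam optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "softmax_cross_entropy", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient bookkeeping on a dynamic tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # keep numpy from hijacking ndarray (op) Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g, a.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g, b.shape)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += _unbroadcast(-g, a.shape)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g * b.data, a.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g * a.data, b.shape)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g / b.data, a.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(-g * a.data / b.data**2, b.shape)

        return self._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities --------------------------------------------------
    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a.grad += g * o * (1.0 - o)

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a.grad += g * (1.0 - o**2)

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a.grad += g * o

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g / a.data

        return self._make(np.log(self.data), (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data > 0

        def backward(g, a=self, pos=pos):
            if a.requires_grad:
                a.grad += g * np.where(pos, 1.0, slope)

        return self._make(np.where(pos, self.data, slope * self.data), (self,), backward)

    def relu(self):
        return self.leaky_relu(slope=0.0)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0))

        def backward(g, a=self, pos=pos, o=out_data):
            if a.requires_grad:
                a.grad += g * np.where(pos, 1.0, o + alpha)

        return self._make(out_data, (self,), backward)

    # -- reductions and shape ops ---------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self):
            if a.requires_grad:
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                a.grad += np.broadcast_to(gg, a.shape)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g.reshape(a.shape)

        return self._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += np.swapaxes(g, ax1, ax2)

        return self._make(np.swapaxes(self.data, ax1, ax2), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self):
            if a.requires_grad:
                np.add.at(a.grad, idx, g)

        return self._make(self.data[idx], (self,), backward)

    # -- backward pass ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: tapes can exceed the recursion limit
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
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(grad, dtype=float).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Differentiable concatenation along ``axis``."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, parts=tuple(tensors)):
        for part, gpart in zip(parts, np.split(g, splits, axis=axis)):
            if part.requires_grad:
                part.grad += gpart

    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy of ``logits`` (B x C) against integer ``labels``.

    Returns the scalar loss tensor and the (detached) class probabilities.
    Fused for numerical stability; gradient is (softmax - onehot) / B.
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    b = len(labels)
    nll = -np.log(probs[np.arange(b), labels] + 1e-300)
    loss_data = nll.mean()

    def backward(g, a=logits, p=probs, y=np.asarray(labels)):
        if a.requires_grad:
            grad = p.copy()
            grad[np.arange(len(y)), y] -= 1.0
            a.grad += g * grad / len(y)

    out = Tensor(loss_data, requires_grad=logits.requires_grad)
    if out.requires_grad:
        out._parents = (logits,)
        out._backward = backward
    return out, probs


class Adam:
    """Adam optimizer with decoupled-from-nothing classic L2 weight decay.

    Weight decay is added to the gradient (the original Adam + L2 recipe).
    """

    def __init__(self, params: list[Tensor], lr: float = 5e-4, betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
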