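"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the classifier families in this package:
broadcast-aware elementwise arithmetic, (batched) matmul, the usual
activations, reductions, indexing/gather, an ``unfold`` primitive for
convolution via im2col, and a fused max-pool.  Gradients accumulate into
``Tensor.grad`` on a topologically sorted backward pass; every backward
rule is validated against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = True, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------- plumbing
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------ elementwise ops
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)

    def __add__(self, other):
        other = self._coerce(other)

        def back(g):
            self._accumulate(g)
            other._accumulate(g)

        return Tensor(self.data + other.data, parents=(self, other), backward=back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=back)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def back(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return Tensor(self.data * other.data, parents=(self, other), backward=back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        def back(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(self.data**exponent, parents=(self,), backward=back)

    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=back)

    def log(self):
        def back(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=back)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor(out_data, parents=(self,), backward=back)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def back(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=back)

    def relu(self):
        mask = self.data > 0

        def back(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=back)

    # --------------------------------------------------------- linear algebra
    def __matmul__(self, other):
        other = self._coerce(other)

        def back(g):
            a, b = self.data, other.data
            if b.ndim == 1:  # (..., k) @ (k,) -> (...)
                ga = np.expand_dims(g, -1) * b
                gb = a * np.expand_dims(g, -1)
            elif a.ndim == 1:  # (k,) @ (..., k, m) -> (..., m)
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.einsum("k,...m->...km", a, g)
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        return Tensor(self.data @ other.data, parents=(self, other), backward=back)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=back
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; the gradient routes to the first maximal
        entry along that axis."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def back(g):
            gfull = np.zeros_like(self.data)
            gexp = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(gfull, np.expand_dims(idx, axis), gexp, axis=axis)
            self._accumulate(gfull)

        return Tensor(out_data, parents=(self,), backward=back)

    # ------------------------------------------------------- shape & indexing
    def reshape(self, *shape):
        orig = self.data.shape

        def back(g):
            self._accumulate(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=back)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def back(g):
            self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=back)

    def __getitem__(self, key):
        def back(g):
            gfull = np.zeros_like(self.data)
            np.add.at(gfull, key, g)
            self._accumulate(gfull)

        return Tensor(self.data[key], parents=(self,), backward=back)

    def take(self, indices: np.ndarray):
        """Gather rows along axis 0 (embedding lookup); scatter-add on
        backward."""
        indices = np.asarray(indices)

        def back(g):
            gfull = np.zeros_like(self.data)
            np.add.at(gfull, indices, g)
            self._accumulate(gfull)

        return Tensor(self.data[indices], parents=(self,), backward=back)

    def take_along_time(self, indices: np.ndarray):
        """Per-row gather along axis 1 of a (B, T, ...) tensor; used to
        reverse each sequence within its own valid length."""
        indices = np.asarray(indices)  # (B, T)
        idx = indices.reshape(indices.shape + (1,) * (self.data.ndim - 2))

        def back(g):
            gfull = np.zeros_like(self.data)
            ndim = self.data.ndim
            b = np.arange(self.data.shape[0]).reshape(-1, *([1] * (ndim - 1)))
            trailing = []
            for ax in range(2, ndim):
                shape = [1] * ndim
                shape[ax] = self.data.shape[ax]
                trailing.append(np.arange(self.data.shape[ax]).reshape(shape))
            np.add.at(gfull, (b, idx, *trailing), g)
            self._accumulate(gfull)

        return Tensor(
            np.take_along_axis(self.data, idx, axis=1), parents=(self,), backward=back
        )


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors), backward=back)


def stack_time(tensors: list[Tensor]) -> Tensor:
    """Stack per-timestep (B, H) tensors into (B, T, H)."""
    def back(g):
        for t_idx, t in enumerate(tensors):
            t._accumulate(g[:, t_idx])

    return Tensor(
        np.stack([t.data for t in tensors], axis=1),
        parents=tuple(tensors),
        backward=back,
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (shift by a detached row max)."""
    shift = x - np.max(x.data, axis=axis, keepdims=True)
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    shift = x - m
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from logits and integer labels."""
    labels = np.asarray(labels, dtype=int)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(log_softmax(logits, axis=-1) * onehot).sum() * (1.0 / len(labels))


def unfold1d(x: Tensor, kernel: int, stride: int = 1, pad: int = 0) -> Tensor:
    """im2col for 1-D convolution: (B, C, L) → (B, C*K, L_out)."""
    B, C, L = x.data.shape
    padded = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    Lp = L + 2 * pad
    L_out = (Lp - kernel) // stride + 1
    s = padded.strides
    windows = np.lib.stride_tricks.as_strided(
        padded,
        shape=(B, C, L_out, kernel),
        strides=(s[0], s[1], s[2] * stride, s[2]),
    )
    cols = windows.transpose(0, 1, 3, 2).reshape(B, C * kernel, L_out).copy()

    def back(g):
        gw = g.reshape(B, C, kernel, L_out).transpose(0, 1, 3, 2)
        gpad = np.zeros((B, C, Lp))
        for k in range(kernel):
            idx = np.arange(L_out) * stride + k
            np.add.at(gpad, (slice(None), slice(None), idx), gw[:, :, :, k])
        self_grad = gpad[:, :, pad : pad + L] if pad else gpad
        x._accumulate(self_grad)

    return Tensor(cols, parents=(x,), backward=back)


def maxpool1d(x: Tensor, size: int = 3, stride: int = 2) -> Tensor:
    """Max pooling over the last axis of (B, C, L); gradient to the first
    maximal entry of each window."""
    B, C, L = x.data.shape
    if L < size:
        size = L
    L_out = (L - size) // stride + 1
    contiguous = np.ascontiguousarray(x.data)
    s = contiguous.strides
    windows = np.lib.stride_tricks.as_strided(
        contiguous,
        shape=(B, C, L_out, size),
        strides=(s[0], s[1], s[2] * stride, s[2]),
    )
    idx = np.argmax(windows, axis=-1)
    out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def back(g):
        gfull = np.zeros_like(x.data)
        flat_pos = np.arange(L_out) * stride + idx  # (B, C, L_out)
        bb, cc = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
        np.add.at(
            gfull,
            (bb[..., None], cc[..., None], flat_pos),
            g,
        )
        x._accumulate(gfull)

    return Tensor(out_data, parents=(x,), backward=back)
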