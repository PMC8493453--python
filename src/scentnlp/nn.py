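"""Neural-network building blocks on top of :mod:`scentnlp.autodiff`.

Layers keep their parameters as :class:`~scentnlp.autodiff.Tensor` leaves;
``Module.parameters()`` walks the tree for the optimizer.  Modules carry a
``training`` flag (dropout and batch-norm behave differently at inference).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, softmax, stack_time, unfold1d

NEG_INF = -1e30


class Module:
    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.asarray(a, dtype=np.float64)


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(glorot(rng, (n_in, n_out)))
        self.bias = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(
        self,
        n_tokens: int,
        dim: int,
        rng: np.random.Generator,
        init: np.ndarray | None = None,
        trainable: bool = True,
    ):
        data = (
            np.array(init, dtype=np.float64)
            if init is not None
            else rng.normal(0, 0.02, size=(n_tokens, dim))
        )
        if data.shape != (n_tokens, dim):
            raise ValueError("embedding init shape mismatch")
        self.table = Tensor(data, requires_grad=trainable)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.table.take(np.asarray(ids, dtype=int))


class Conv1d(Module):
    """1-D convolution over (B, C, L) with 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.weight = Tensor(glorot(rng, (c_in * kernel, c_out)))
        self.bias = Tensor(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        cols = unfold1d(x, self.kernel, stride=1, pad=self.kernel // 2)
        # (B, L, C*K) @ (C*K, C_out) -> (B, L, C_out) -> (B, C_out, L)
        y = cols.transpose(0, 2, 1) @ self.weight + self.bias
        return y.transpose(0, 2, 1)


class BatchNorm(Module):
    """Batch normalization over the batch (and, for sequences, length)
    axes; running statistics are used at inference."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features))
        self.beta = Tensor(np.zeros(n_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def __call__(self, x: Tensor) -> Tensor:
        # features on axis 1 for (B, C, L), axis -1 for (B, F)
        if x.ndim == 3:
            axes, shape = (0, 2), (1, -1, 1)
        else:
            axes, shape = (0,), (1, -1)
        if self.training:
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            n = x.data.size / x.data.shape[1 if x.ndim == 3 else -1]
            mu = x.sum(axis=axes[0], keepdims=True)
            for ax in axes[1:]:
                mu = mu.sum(axis=ax, keepdims=True)
            mu = mu * (1.0 / n)
            centered = x - mu
            sq = centered * centered
            v = sq.sum(axis=axes[0], keepdims=True)
            for ax in axes[1:]:
                v = v.sum(axis=ax, keepdims=True)
            v = v * (1.0 / n)
            xhat = centered * (v + self.eps) ** -0.5
        else:
            xhat = (x - self.running_mean.reshape(shape)) * (
                (self.running_var.reshape(shape) + self.eps) ** -0.5
            )
        return xhat * self.gamma.reshape(*shape) + self.beta.reshape(*shape)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim))
        self.beta = Tensor(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * keep


def lstm_cell(
    h_prev: Tensor, c_prev: Tensor, x_t: Tensor, weight: Tensor, bias: Tensor
) -> tuple[Tensor, Tensor]:
    """One LSTM step on a batch.

    Gate pre-activations come from ``[h_{t-1}, x_t] @ W + b`` split into
    input/forget/node/output quarters; then

        c_t = f_t * c_{t-1} + i_t * g_t,   h_t = o_t * tanh(c_t).
    """
    units = h_prev.shape[-1]
    z = concat([h_prev, x_t], axis=-1) @ weight + bias
    i = z[:, 0 * units : 1 * units].sigmoid()
    f = z[:, 1 * units : 2 * units].sigmoid()
    g = z[:, 2 * units : 3 * units].tanh()
    o = z[:, 3 * units : 4 * units].sigmoid()
    c = f * c_prev + i * g
    h = o * c.tanh()
    return h, c


class LSTMLayer(Module):
    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.weight = Tensor(glorot(rng, (n_in + units, 4 * units)))
        bias = np.zeros(4 * units)
        bias[units : 2 * units] = 1.0  # forget-gate bias keeps early memory
        self.bias = Tensor(bias)

    def __call__(self, x: Tensor) -> Tensor:
        """(B, T, n_in) → (B, T, units)."""
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.units)), requires_grad=False)
        c = Tensor(np.zeros((B, self.units)), requires_grad=False)
        outs = []
        for t in range(T):
            h, c = lstm_cell(h, c, x[:, t, :], self.weight, self.bias)
            outs.append(h)
        return stack_time(outs)


class AttentionPool(Module):
    """Additive attention pooling with a learned context vector:
    u_i = tanh(W_u h_i + b_u); α = softmax(u_i · u_c); v = Σ α_i h_i."""

    def __init__(self, dim: int, context_dim: int, rng: np.random.Generator):
        self.proj = Linear(dim, context_dim, rng)
        self.context = Tensor(rng.normal(0, 0.1, size=(context_dim,)))

    def __call__(self, hidden: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        """(B, T, d) (+ optional boolean pad mask (B, T), True = pad) → (B, d)."""
        u = self.proj(hidden).tanh()
        scores = u @ self.context  # (B, T)
        if pad_mask is not None:
            scores = scores + np.where(pad_mask, NEG_INF, 0.0)
        alpha = softmax(scores, axis=-1)
        return (alpha.reshape(*alpha.shape, 1) * hidden).sum(axis=1)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError(f"model dim {dim} not divisible by {heads} heads")
        self.heads = heads
        self.d_k = dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        B, T, d = x.shape
        def split(t: Tensor) -> Tensor:  # (B, T, d) -> (B, H, T, d_k)
            return t.reshape(B, T, self.heads, self.d_k).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_k))
        if pad_mask is not None:
            scores = scores + np.where(pad_mask, NEG_INF, 0.0)[:, None, None, :]
        attn = softmax(scores, axis=-1)
        out = attn @ v  # (B, H, T, d_k)
        return self.wo(out.transpose(0, 2, 1, 3).reshape(B, T, d))


class Adam:
    """Adam optimizer (β1=0.9, β2=0.999, ε=1e-8 by default)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
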