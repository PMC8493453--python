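"""The three classifier families and the shared training loop.

* A deep CNN over static word embeddings: a stem summing two stacked
  3-kernel convolutions (with batch norm) and a 1-kernel projection, then
  repeated blocks of max-pool (size 3, stride 2) + two 3-kernel
  convolutions with an identity shortcut, a global max-pool, and a
  batch-norm + dropout softmax head.
* A multi-layer (optionally bidirectional) LSTM with shortcut connections
  between layers and additive attention pooling over the final hidden
  states.
* A transformer encoder (multi-head scaled dot-product self-attention,
  position-wise feed-forward, residual + layer norm) classifying from the
  first-position [CLS] representation.

Training uses Adam and, for CNN/LSTM, a reduce-on-plateau learning-rate
schedule: the rate is multiplied by 0.7 whenever the validation loss fails
to decrease within one epoch.

Padding is excluded from every pooling/attention statistic by masking, so
model outputs are independent of how far a batch is padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import nn
from .autodiff import Tensor, concat, cross_entropy, maxpool1d, softmax
from .embeddings import EmbeddingMatrix, sinusoidal_positions
from .nn import NEG_INF

# ----------------------------------------------------------- functional ops


@dataclass
class LSTMState:
    """Hidden/memory state plus last-step gate activations."""

    h: np.ndarray
    c: np.ndarray
    f: np.ndarray | None = None
    i: np.ndarray | None = None
    g: np.ndarray | None = None
    o: np.ndarray | None = None


@dataclass
class LSTMParams:
    """Stacked gate parameters: ``[h, x] @ weight + bias`` with the four
    quarters ordered input, forget, node, output."""

    weight: np.ndarray  # (units + n_in, 4 * units)
    bias: np.ndarray  # (4 * units,)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def lstm_step(state: LSTMState, x_t: np.ndarray, params: LSTMParams) -> LSTMState:
    """One exact LSTM cell update:

    f_t, i_t, o_t = σ(·), g_t = tanh(·),
    c_t = f_t ⊙ c_{t-1} + i_t ⊙ g_t,  h_t = o_t ⊙ tanh(c_t).
    """
    h, c = np.asarray(state.h, float), np.asarray(state.c, float)
    x_t = np.asarray(x_t, float)
    units = h.shape[-1]
    if params.weight.shape != (units + x_t.shape[-1], 4 * units):
        raise ValueError(
            f"weight shape {params.weight.shape} incompatible with "
            f"units={units}, n_in={x_t.shape[-1]}"
        )
    z = np.concatenate([h, x_t], axis=-1) @ params.weight + params.bias
    i = _sigmoid(z[..., 0 * units : 1 * units])
    f = _sigmoid(z[..., 1 * units : 2 * units])
    g = np.tanh(z[..., 2 * units : 3 * units])
    o = _sigmoid(z[..., 3 * units : 4 * units])
    c_new = f * c + i * g
    h_new = o * np.tanh(c_new)
    return LSTMState(h=h_new, c=c_new, f=f, i=i, g=g, o=o)


def attention_pool(
    hidden_states: np.ndarray,
    w_u: np.ndarray,
    b_u: np.ndarray,
    u_c: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Additive attention pooling: u_i = tanh(W_u h_i + b_u),
    α = softmax(u_i · u_c), v = Σ α_i h_i.

    Returns ``(v, α)``; the weights sum to 1.
    """
    h = np.asarray(hidden_states, float)
    if h.ndim != 2 or h.shape[0] == 0:
        raise ValueError("hidden_states must be a non-empty (T, d) array")
    u = np.tanh(h @ w_u + b_u)
    scores = u @ u_c
    scores = scores - scores.max()
    alpha = np.exp(scores) / np.exp(scores).sum()
    return alpha @ h, alpha


def scaled_dot_attention(
    q: np.ndarray, k: np.ndarray, v: np.ndarray, return_weights: bool = False
):
    """softmax(QKᵀ/√d_k)V — each output row is a convex combination of the
    value rows."""
    q, k, v = (np.asarray(a, float) for a in (q, k, v))
    if q.shape[-1] != k.shape[-1] or k.shape[-2] != v.shape[-2]:
        raise ValueError("attention dimension mismatch")
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(k.shape[-1])
    scores = scores - scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w = w / w.sum(axis=-1, keepdims=True)
    out = w @ v
    return (out, w) if return_weights else out


# ------------------------------------------------------------------- configs

EMBEDDING_MODES = ("random", "fixed_pretrained", "trainable_pretrained")


@dataclass
class CNNConfig:
    channels: int = 250
    block_repeats: int = 6
    kernel: int = 3
    pool_size: int = 3
    pool_stride: int = 2
    dropout: float = 0.5
    embedding_mode: str = "trainable_pretrained"
    n_classes: int = 3
    max_len: int = 2240

    def validate(self) -> None:
        if self.block_repeats < 1:
            raise ValueError("block_repeats must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.embedding_mode not in EMBEDDING_MODES:
            raise ValueError(f"embedding_mode must be one of {EMBEDDING_MODES}")


@dataclass
class LSTMConfig:
    layers: int = 5
    units: int = 650  # per direction when bidirectional (310 x 2 at full scale)
    bidirectional: bool = False
    shortcuts: tuple[tuple[int, int], ...] = ((1, 3), (3, 5))
    dropout: float = 0.5
    attention_dim: int | None = None
    n_classes: int = 3
    max_len: int = 2240

    def validate(self) -> None:
        for src, dst in self.shortcuts:
            if not (1 <= src < dst <= self.layers):
                raise ValueError(f"bad shortcut ({src}, {dst}) for {self.layers} layers")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TransformerConfig:
    layers: int = 12
    heads: int = 12
    dim: int = 768
    d_ff: int = 3072
    dropout: float = 0.1
    n_segments: int = 2
    n_classes: int = 3
    max_len: int = 512

    def validate(self) -> None:
        if self.dim % self.heads != 0:
            raise ValueError("dim must equal heads * d_k")
        if self.d_ff < self.dim:
            raise ValueError("d_ff must be >= dim")
        if self.dim % 2 != 0:
            raise ValueError("dim must be even for sinusoidal positions")

    @property
    def d_k(self) -> int:
        return self.dim // self.heads


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    decay_factor: float | None = 0.7  # None: fixed rate (transformer)
    patience: int = 1
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    grad_clip: float | None = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.decay_factor is not None and not 0.0 < self.decay_factor < 1.0:
            raise ValueError("decay factor must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


# -------------------------------------------------------------------- models


def _pad_batch(
    id_lists: Sequence[Sequence[int]], pad_id: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Pad to the batch maximum; returns (ids, valid_mask)."""
    max_len = max((len(ids) for ids in id_lists), default=1) or 1
    out = np.full((len(id_lists), max_len), pad_id, dtype=int)
    mask = np.zeros((len(id_lists), max_len), dtype=bool)
    for r, ids in enumerate(id_lists):
        out[r, : len(ids)] = ids
        mask[r, : len(ids)] = True
    return out, mask


class CNNClassifier(nn.Module):
    def __init__(
        self,
        config: CNNConfig,
        vocab_size: int,
        emb_dim: int,
        seed: int = 0,
        embedding_init: np.ndarray | None = None,
    ):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        trainable = config.embedding_mode != "fixed_pretrained"
        if config.embedding_mode != "random" and embedding_init is None:
            raise ValueError("pretrained embedding modes require an init matrix")
        self.embedding = nn.Embedding(
            vocab_size,
            emb_dim,
            rng,
            init=embedding_init if config.embedding_mode != "random" else None,
            trainable=trainable,
        )
        C = config.channels
        self.stem_conv1 = nn.Conv1d(emb_dim, C, config.kernel, rng)
        self.stem_bn1 = nn.BatchNorm(C)
        self.stem_conv2 = nn.Conv1d(C, C, config.kernel, rng)
        self.stem_bn2 = nn.BatchNorm(C)
        self.stem_proj = nn.Conv1d(emb_dim, C, 1, rng)  # 1-kernel, no BN
        self.block_convs = []
        self.block_bns = []
        for _ in range(config.block_repeats):
            self.block_convs.append(
                [nn.Conv1d(C, C, config.kernel, rng), nn.Conv1d(C, C, config.kernel, rng)]
            )
            self.block_bns.append([nn.BatchNorm(C), nn.BatchNorm(C)])
        self.head_bn = nn.BatchNorm(C)
        self.head_drop = nn.Dropout(config.dropout, rng)
        self.head = nn.Linear(C, config.n_classes, rng)

    def parameters(self) -> list[Tensor]:
        params = super().parameters()
        for pair in self.block_convs + self.block_bns:
            for mod in pair:
                params.extend(mod.parameters())
        return params

    def train(self, mode: bool = True) -> "CNNClassifier":
        super().train(mode)
        for pair in self.block_convs + self.block_bns:
            for mod in pair:
                mod.train(mode)
        return self

    def forward(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        cfg = self.config
        lens = np.maximum(mask.sum(axis=1), 1)
        x = self.embedding(ids) * mask[:, :, None]
        x = x.transpose(0, 2, 1)  # (B, E, L)
        chan_mask = mask[:, None, :].astype(float)
        # re-zero padding after every conv: bias/BN would otherwise leak
        # nonzero values into pad positions that the next kernel reads
        branch = self.stem_bn1(self.stem_conv1(x)).relu() * chan_mask
        branch = self.stem_bn2(self.stem_conv2(branch)).relu() * chan_mask
        x = (branch + self.stem_proj(x)) * chan_mask
        for convs, bns in zip(self.block_convs, self.block_bns):
            L = x.shape[2]
            if L >= cfg.pool_size:
                x = x + np.where(chan_mask > 0, 0.0, NEG_INF)
                x = maxpool1d(x, cfg.pool_size, cfg.pool_stride)
                # only windows fully inside a sample's valid span count, so
                # the features do not depend on how far the batch is padded
                lens = np.maximum((lens - cfg.pool_size) // cfg.pool_stride + 1, 1)
                lens = np.minimum(lens, x.shape[2])
                valid = np.arange(x.shape[2])[None, :] < lens[:, None]
                chan_mask = valid[:, None, :].astype(float)
                x = x * chan_mask
            h = bns[0](convs[0](x)).relu() * chan_mask
            h = bns[1](convs[1](h)).relu() * chan_mask
            x = (x + h) * chan_mask
        x = x + np.where(chan_mask > 0, 0.0, NEG_INF)
        pooled = x.max(axis=2)  # (B, C)
        pooled = self.head_bn(pooled)
        pooled = self.head_drop(pooled)
        return self.head(pooled)


class LSTMClassifier(nn.Module):
    def __init__(
        self,
        config: LSTMConfig,
        vocab_size: int,
        emb_dim: int,
        seed: int = 0,
        embedding_init: np.ndarray | None = None,
    ):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.embedding = nn.Embedding(
            vocab_size, emb_dim, rng, init=embedding_init, trainable=True
        )
        width = config.units * (2 if config.bidirectional else 1)
        self.fwd_layers = []
        self.bwd_layers = []
        for layer in range(config.layers):
            n_in = emb_dim if layer == 0 else width
            self.fwd_layers.append(nn.LSTMLayer(n_in, config.units, rng))
            if config.bidirectional:
                self.bwd_layers.append(nn.LSTMLayer(n_in, config.units, rng))
        self.dropout = nn.Dropout(config.dropout, rng)
        self.attention = nn.AttentionPool(width, config.attention_dim or width, rng)
        self.head = nn.Linear(width, config.n_classes, rng)

    def parameters(self) -> list[Tensor]:
        params = super().parameters()
        for mod in self.fwd_layers + self.bwd_layers:
            params.extend(mod.parameters())
        return params

    def train(self, mode: bool = True) -> "LSTMClassifier":
        super().train(mode)
        for mod in self.fwd_layers + self.bwd_layers:
            mod.train(mode)
        return self

    @staticmethod
    def _reverse_indices(mask: np.ndarray) -> np.ndarray:
        """Per-sample time indices that reverse the valid prefix and leave
        padding in place."""
        B, T = mask.shape
        lens = np.maximum(mask.sum(axis=1), 1)
        t = np.tile(np.arange(T), (B, 1))
        rev = lens[:, None] - 1 - t
        return np.where(t < lens[:, None], rev, t)

    def forward(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        cfg = self.config
        x = self.embedding(ids) * mask[:, :, None]
        rev_idx = self._reverse_indices(mask) if cfg.bidirectional else None
        outputs: dict[int, Tensor] = {}
        inp = self.dropout(x)
        for layer in range(1, cfg.layers + 1):
            h = self.fwd_layers[layer - 1](inp)
            if cfg.bidirectional:
                h_rev = self.bwd_layers[layer - 1](inp.take_along_time(rev_idx))
                h = concat([h, h_rev.take_along_time(rev_idx)], axis=-1)
            outputs[layer] = h
            if layer < cfg.layers:
                inp = self.dropout(h)
                for src, dst in cfg.shortcuts:
                    if dst == layer + 1:
                        inp = inp + outputs[src]
        pooled = self.attention(outputs[cfg.layers], pad_mask=~mask)
        return self.head(pooled)


class TransformerClassifier(nn.Module):
    def __init__(self, config: TransformerConfig, vocab_size: int, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.token_emb = nn.Embedding(vocab_size, config.dim, rng)
        self.segment_emb = nn.Embedding(config.n_segments, config.dim, rng)
        self.positions = sinusoidal_positions(config.max_len, config.dim)
        self.attn_layers = []
        self.ffn1 = []
        self.ffn2 = []
        self.ln1 = []
        self.ln2 = []
        for _ in range(config.layers):
            self.attn_layers.append(nn.MultiHeadSelfAttention(config.dim, config.heads, rng))
            self.ffn1.append(nn.Linear(config.dim, config.d_ff, rng))
            self.ffn2.append(nn.Linear(config.d_ff, config.dim, rng))
            self.ln1.append(nn.LayerNorm(config.dim))
            self.ln2.append(nn.LayerNorm(config.dim))
        self.dropout = nn.Dropout(config.dropout, rng)
        self.pooler = nn.Linear(config.dim, config.dim, rng)
        self.head = nn.Linear(config.dim, config.n_classes, rng)

    def parameters(self) -> list[Tensor]:
        params = super().parameters()
        for group in (self.attn_layers, self.ffn1, self.ffn2, self.ln1, self.ln2):
            for mod in group:
                params.extend(mod.parameters())
        return params

    def train(self, mode: bool = True) -> "TransformerClassifier":
        super().train(mode)
        for group in (self.attn_layers, self.ffn1, self.ffn2, self.ln1, self.ln2):
            for mod in group:
                mod.train(mode)
        return self

    def forward(
        self, ids: np.ndarray, mask: np.ndarray, segment_ids: np.ndarray | None = None
    ) -> Tensor:
        cfg = self.config
        B, T = ids.shape
        if T > cfg.max_len:
            raise ValueError(f"sequence length {T} exceeds max positions {cfg.max_len}")
        if segment_ids is None:
            segment_ids = np.zeros_like(ids)
        x = self.token_emb(ids) + self.segment_emb(segment_ids) + self.positions[:T]
        x = self.dropout(x)
        pad = ~mask
        for attn, f1, f2, ln1, ln2 in zip(
            self.attn_layers, self.ffn1, self.ffn2, self.ln1, self.ln2
        ):
            x = ln1(x + self.dropout(attn(x, pad_mask=pad)))
            x = ln2(x + self.dropout(f2(f1(x).relu())))
        cls = x[:, 0, :]
        pooled = self.pooler(cls).tanh()
        return self.head(self.dropout(pooled))


# ------------------------------------------------------------------ builders


def build_cnn(
    config: CNNConfig,
    embeddings: EmbeddingMatrix | None = None,
    vocab_size: int | None = None,
    emb_dim: int | None = None,
    seed: int = 0,
) -> CNNClassifier:
    if embeddings is not None:
        vocab_size, emb_dim = embeddings.vectors.shape
        init = embeddings.vectors
    else:
        init = None
        if vocab_size is None or emb_dim is None:
            raise ValueError("vocab_size and emb_dim required without embeddings")
    return CNNClassifier(config, vocab_size, emb_dim, seed=seed, embedding_init=init)


def build_lstm(
    config: LSTMConfig,
    embeddings: EmbeddingMatrix | None = None,
    vocab_size: int | None = None,
    emb_dim: int | None = None,
    seed: int = 0,
) -> LSTMClassifier:
    if embeddings is not None:
        vocab_size, emb_dim = embeddings.vectors.shape
        init = embeddings.vectors
    else:
        init = None
        if vocab_size is None or emb_dim is None:
            raise ValueError("vocab_size and emb_dim required without embeddings")
    return LSTMClassifier(config, vocab_size, emb_dim, seed=seed, embedding_init=init)


def build_transformer(
    config: TransformerConfig, vocab_size: int, seed: int = 0
) -> TransformerClassifier:
    return TransformerClassifier(config, vocab_size, seed=seed)


# ------------------------------------------------------------ training loop


def plateau_lr_schedule(
    val_losses: Sequence[float],
    initial_lr: float,
    factor: float = 0.7,
    patience: int = 1,
) -> list[float]:
    """Learning rate in effect *after* each epoch under the
    multiply-by-``factor``-on-no-improvement rule.

    The best validation loss so far is tracked; whenever the loss fails to
    improve (decrease) for ``patience`` consecutive epochs, the rate is
    multiplied by ``factor``.
    """
    lr = initial_lr
    best = np.inf
    stall = 0
    out = []
    for loss in val_losses:
        if loss < best:
            best = loss
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                lr *= factor
                stall = 0
        out.append(lr)
    return out


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return self.epochs


def _batches(n: int, batch_size: int, rng: np.random.Generator | None):
    order = np.arange(n) if rng is None else rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _epoch_loss(model, data, batch_size: int) -> float:
    ids, labels = data
    model.eval()
    total, count = 0.0, 0
    for idx in _batches(len(ids), batch_size, None):
        batch_ids = [ids[i] for i in idx]
        x, mask = _pad_batch(batch_ids)
        logits = model.forward(x, mask)
        loss = cross_entropy(logits, np.asarray(labels)[idx])
        total += float(loss.data) * len(idx)
        count += len(idx)
    return total / max(count, 1)


def train_classifier(
    model: nn.Module,
    train_data: tuple[list[list[int]], list[int]],
    valid_data: tuple[list[list[int]], list[int]],
    tc: TrainConfig,
) -> TrainHistory:
    """Train a classifier with Adam and (optionally) plateau LR decay.

    ``train_data``/``valid_data`` are (token-id lists, integer labels).
    History records per-epoch train/validation loss and the learning rate
    in effect for the *next* epoch.  Deterministic under ``tc.seed``.

    Raises
    ------
    RuntimeError
        If the loss becomes non-finite (with a diagnostic).
    """
    tc.validate()
    ids, labels = train_data
    if not ids:
        raise ValueError("empty training data")
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(tc.seed)
    opt = nn.Adam(
        model.parameters(), tc.learning_rate, beta1=tc.beta1, beta2=tc.beta2, eps=tc.eps
    )
    history = TrainHistory()
    best_val = np.inf
    stall = 0
    for epoch in range(1, tc.epochs + 1):
        model.train()
        total, count = 0.0, 0
        for idx in _batches(len(ids), tc.batch_size, rng):
            batch_ids = [ids[i] for i in idx]
            x, mask = _pad_batch(batch_ids)
            logits = model.forward(x, mask)
            loss = cross_entropy(logits, labels[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {count // tc.batch_size}: "
                    f"{float(loss.data)!r}"
                )
            opt.zero_grad()
            loss.backward()
            if tc.grad_clip is not None:
                norm = np.sqrt(
                    sum(float((p.grad**2).sum()) for p in opt.params if p.grad is not None)
                )
                if norm > tc.grad_clip:
                    scale = tc.grad_clip / (norm + 1e-12)
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad = p.grad * scale
            opt.step()
            total += float(loss.data) * len(idx)
            count += len(idx)
        train_loss = total / count
        val_loss = _epoch_loss(model, valid_data, tc.batch_size) if valid_data[0] else np.nan
        if tc.decay_factor is not None and valid_data[0]:
            if val_loss < best_val:
                best_val = val_loss
                stall = 0
            else:
                stall += 1
                if stall >= tc.patience:
                    opt.lr *= tc.decay_factor
                    stall = 0
        history.epochs.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "val_loss": float(val_loss),
                "lr": opt.lr,
            }
        )
    model.eval()
    return history


def predict_proba(
    model: nn.Module, id_lists: Sequence[Sequence[int]], batch_size: int = 32
) -> np.ndarray:
    """Class-probability matrix, one row per document (rows sum to 1).

    Empty token sequences cannot be scored by the networks; such rows fall
    back to the uniform distribution rather than aborting the batch.
    """
    model.eval()
    n = len(id_lists)
    out = np.full((n, 3), 1.0 / 3)
    keep = [i for i, ids in enumerate(id_lists) if len(ids) > 0]
    for start in range(0, len(keep), batch_size):
        idx = keep[start : start + batch_size]
        x, mask = _pad_batch([id_lists[i] for i in idx])
        logits = model.forward(x, mask)
        probs = softmax(logits, axis=-1).data
        out[idx] = probs
    return out
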