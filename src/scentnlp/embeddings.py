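"""Skip-gram negative-sampling (SGNS) word embeddings and transformer
input embeddings.

SGNS trains input vectors ``v_w`` and output vectors ``v'_w`` so that
observed (center, context) pairs score high under a sigmoid of their dot
product while ``n`` noise words drawn from the unigram distribution raised
to the 3/4 power score low:

    loss(I, O, negs) = -log σ(v'_O · v_I) - Σ_neg log σ(-v'_neg · v_I)

Transformer inputs are the sum of token, segment, and fixed sinusoidal
position embeddings:

    PE(p, 2i)   = sin(p / 10000^(2i/d))
    PE(p, 2i+1) = cos(p / 10000^(2i/d))
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .tokenization import PAD, UNK


@dataclass
class SGNSConfig:
    dimension: int = 300
    context_size: int = 5
    negatives: int = 5
    epochs: int = 3
    learning_rate: float = 0.025
    seed: int = 0

    def validate(self) -> None:
        for name in ("dimension", "context_size", "negatives"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EmbeddingMatrix:
    """Word-vector table row-aligned to a word list.

    ``vectors`` are the input representations ``v_w`` (what downstream
    models consume); ``output_vectors`` are the context-side ``v'_w``.
    """

    words: list[str]
    vectors: np.ndarray
    output_vectors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.word_to_id = {w: i for i, w in enumerate(self.words)}
        if self.vectors.shape[0] != len(self.words):
            raise ValueError("row count must equal vocabulary size")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.word_to_id[word]]

    def cosine(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb) + 1e-12))

    def save(self, path: str | Path) -> None:
        """word2vec text format: header ``count dim``, then one word+vector
        per line."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.words)} {self.dimension}\n")
            for w, row in zip(self.words, self.vectors):
                fh.write(w + " " + " ".join(f"{x:.8g}" for x in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingMatrix":
        with Path(path).open("r", encoding="utf-8") as fh:
            n, d = map(int, fh.readline().split())
            words, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                words.append(parts[0])
                rows.append([float(x) for x in parts[1 : d + 1]])
        if len(words) != n:
            raise ValueError("corrupt embedding file: row count mismatch")
        return cls(words=words, vectors=np.asarray(rows, dtype=np.float64))


def negative_sampling_dist(freqs: Mapping[str, int] | Sequence[int]) -> np.ndarray:
    """Noise distribution for negative sampling: P(w) ∝ count(w)^(3/4).

    Accepts a word→count mapping (probabilities follow its iteration
    order) or a plain count sequence.  Sums to 1 within 1e-12.
    """
    counts = np.asarray(
        list(freqs.values()) if isinstance(freqs, Mapping) else freqs, dtype=float
    )
    if counts.size == 0 or np.any(counts < 0):
        raise ValueError("counts must be non-negative and non-empty")
    if not np.any(counts > 0):
        raise ValueError("at least one count must be positive")
    weights = counts**0.75
    return weights / weights.sum()


def sgns_pair_loss(
    v_in: np.ndarray, v_pos: np.ndarray, v_negs: np.ndarray
) -> float:
    """Per-pair negative-sampling loss for one (center, context) pair."""
    pos = -np.log(_sigmoid(v_pos @ v_in) + 1e-12)
    neg = -np.log(_sigmoid(-(v_negs @ v_in)) + 1e-12).sum()
    return float(pos + neg)


def sgns_pair_grad(
    v_in: np.ndarray, v_pos: np.ndarray, v_negs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`sgns_pair_loss` w.r.t. all vectors."""
    g_pos = _sigmoid(v_pos @ v_in) - 1.0
    g_negs = _sigmoid(v_negs @ v_in)
    d_in = g_pos * v_pos + g_negs @ v_negs
    d_pos = g_pos * v_in
    d_negs = np.outer(g_negs, v_in)
    return d_in, d_pos, d_negs


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def train_sgns(
    token_stream: Sequence[Sequence[str]],
    config: SGNSConfig,
    words: list[str] | None = None,
) -> EmbeddingMatrix:
    """Train SGNS embeddings over a stream of token lists.

    Plain SGD with a linearly decaying learning rate; negatives drawn from
    the 3/4-power unigram distribution; deterministic under
    ``config.seed``.  With ``epochs=0`` the seeded random initialization is
    returned unchanged.
    """
    config.validate()
    sentences = [list(s) for s in token_stream if len(s) > 0]
    if not sentences:
        raise ValueError("token stream is empty")
    freq: Counter[str] = Counter()
    for s in sentences:
        freq.update(s)
    if words is None:
        words = [PAD, UNK] + sorted(freq, key=lambda w: (-freq[w], w))
    word_to_id = {w: i for i, w in enumerate(words)}
    counts = np.array([freq.get(w, 0) for w in words], dtype=float)
    noise = negative_sampling_dist(np.maximum(counts, 0))
    rng = np.random.default_rng(config.seed)
    d = config.dimension
    vec_in = (rng.random((len(words), d)) - 0.5) / d
    vec_out = np.zeros((len(words), d))
    if config.epochs == 0:
        return EmbeddingMatrix(words=words, vectors=vec_in, output_vectors=vec_out)

    total_pairs = sum(
        max(len(s) - 1, 0) * 2 * config.context_size for s in sentences
    ) * config.epochs
    lr0, done = config.learning_rate, 0
    for _epoch in range(config.epochs):
        for sent in sentences:
            ids = [word_to_id[w] for w in sent if w in word_to_id]
            for t, center in enumerate(ids):
                lo = max(0, t - config.context_size)
                hi = min(len(ids), t + config.context_size + 1)
                for o in range(lo, hi):
                    if o == t:
                        continue
                    lr = lr0 * max(1.0 - done / max(total_pairs, 1), 1e-4)
                    done += 1
                    negs = rng.choice(len(words), size=config.negatives, p=noise)
                    targets = np.concatenate(([ids[o]], negs))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    vi = vec_in[center]
                    vo = vec_out[targets]
                    g = _sigmoid(vo @ vi) - labels
                    vec_in[center] = vi - lr * (g @ vo)
                    vec_out[targets] = vo - lr * np.outer(g, vi)
    if not (np.all(np.isfinite(vec_in)) and np.all(np.isfinite(vec_out))):
        raise RuntimeError("SGNS training diverged to non-finite vectors")
    return EmbeddingMatrix(words=words, vectors=vec_in, output_vectors=vec_out)


# ------------------------------------------------------- position embeddings


def position_embedding(p: int, dim_index: int, d: int) -> float:
    """Sinusoidal position value: sine on even dimensions, cosine on odd,
    both of the angle ``p / 10000^(2i/d)`` with ``i = dim_index // 2``."""
    if not 0 <= dim_index < d:
        raise ValueError(f"dim_index {dim_index} out of range for d={d}")
    i = dim_index // 2
    angle = p / 10000 ** (2 * i / d)
    return float(np.sin(angle) if dim_index % 2 == 0 else np.cos(angle))


def sinusoidal_positions(n_positions: int, d: int) -> np.ndarray:
    """Full ``(n_positions, d)`` sinusoidal position table."""
    if d % 2 != 0:
        raise ValueError("model dimension must be even for sin/cos pairing")
    pos = np.arange(n_positions)[:, None]
    i = np.arange(d // 2)[None, :]
    angles = pos / 10000 ** (2 * i / d)
    table = np.empty((n_positions, d))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles)
    return table


def transformer_input(
    token_ids: Sequence[int],
    segment_ids: Sequence[int],
    token_table: np.ndarray,
    segment_table: np.ndarray,
) -> np.ndarray:
    """Sum of token, segment, and sinusoidal position embeddings; shape
    ``(len, d)``."""
    if len(token_ids) != len(segment_ids):
        raise ValueError(
            f"length mismatch: {len(token_ids)} token ids vs "
            f"{len(segment_ids)} segment ids"
        )
    if token_table.shape[1] != segment_table.shape[1]:
        raise ValueError("token and segment embedding dimensions differ")
    d = token_table.shape[1]
    tok = token_table[np.asarray(token_ids, dtype=int)]
    seg = segment_table[np.asarray(segment_ids, dtype=int)]
    return tok + seg + sinusoidal_positions(len(token_ids), d)
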