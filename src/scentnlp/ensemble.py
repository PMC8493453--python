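"""Soft-voting and hierarchical ensembles.

A *seed ensemble* averages the class-probability matrices of several
trainings of one architecture (soft voting).  Two combined systems sit on
top:

* **SCENT-v1** — soft vote of the static (CNN) ensemble and the contextual
  (transformer) ensemble, classifying by the argmax of the averaged rows.
* **SCENT-v2** — hierarchical rule: the transformer ensemble decides; rows
  it predicts *healthy* are re-decided by a CNN+LSTM soft vote.  Caution
  and critical decisions of the base ensemble are kept untouched, which is
  what pins its false-negative behaviour for the severe classes.

Averaging happens in probability space (post-softmax).  Argmax ties break
toward the more severe class, matching the goal of minimizing false
negatives under the healthy prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .labels import LABEL_TO_INDEX, LABELS, severe_argmax


def check_probability_matrix(p: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[1] != len(LABELS):
        raise ValueError(f"expected (n, {len(LABELS)}) probability matrix, got {p.shape}")
    if np.any(p < -atol) or np.any(p > 1 + atol):
        raise ValueError("probabilities outside [0, 1]")
    if not np.allclose(p.sum(axis=1), 1.0, atol=atol):
        raise ValueError("probability rows must sum to 1")
    return p


@dataclass
class EnsembleSpec:
    """Member bookkeeping for one single-architecture seed ensemble."""

    member_count: int = 10
    member_seeds: tuple[int, ...] = ()
    aggregation: str = "soft-vote"

    def __post_init__(self) -> None:
        if self.member_count < 1:
            raise ValueError("member_count must be >= 1")
        if not self.member_seeds:
            self.member_seeds = tuple(range(self.member_count))


def soft_vote(members: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise arithmetic mean of member probability matrices.

    Invariant to member order; rows of the result still sum to 1.
    """
    if len(members) == 0:
        raise ValueError("soft_vote requires at least one member")
    mats = [check_probability_matrix(m) for m in members]
    shape = mats[0].shape
    for m in mats[1:]:
        if m.shape != shape:
            raise ValueError(f"member shape mismatch: {m.shape} vs {shape}")
    return np.mean(mats, axis=0)


def _indices_to_labels(idx: np.ndarray) -> list[str]:
    return [LABELS[i] for i in idx]


def scent_v1(cnn_ens: np.ndarray, transformer_ens: np.ndarray) -> list[str]:
    """Soft vote of the CNN and transformer ensemble matrices; label is the
    argmax of the two-matrix mean, ties to the more severe class."""
    mean = soft_vote([cnn_ens, transformer_ens])
    return _indices_to_labels(severe_argmax(mean))


def hierarchical_generic(
    base: np.ndarray, override: np.ndarray, gate_class: str
) -> list[str]:
    """Hierarchical ensemble: the base matrix decides every row; rows whose
    base decision equals ``gate_class`` are re-decided by the override
    matrix."""
    if gate_class not in LABEL_TO_INDEX:
        raise ValueError(f"unknown gate class {gate_class!r}")
    base = check_probability_matrix(base)
    override = check_probability_matrix(override)
    if base.shape != override.shape:
        raise ValueError(f"shape mismatch: {base.shape} vs {override.shape}")
    base_pred = severe_argmax(base)
    over_pred = severe_argmax(override)
    gate = LABEL_TO_INDEX[gate_class]
    final = np.where(base_pred == gate, over_pred, base_pred)
    return _indices_to_labels(final)


def scent_v2(
    transformer_ens: np.ndarray, cnn_ens: np.ndarray, lstm_ens: np.ndarray
) -> list[str]:
    """Hierarchical ensemble: transformer ensemble decisions are kept for
    caution/critical; its healthy predictions are re-decided by the
    CNN+LSTM soft vote."""
    override = soft_vote([cnn_ens, lstm_ens])
    return hierarchical_generic(transformer_ens, override, gate_class="healthy")
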