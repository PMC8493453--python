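"""Triage label inventory and severity ordering.

The three ordinal classes a report can receive, ordered from least to most
severe: ``healthy`` (negative class), ``caution`` (caution required) and
``critical``.  Probability matrices everywhere in this package use this
fixed column order.
"""

from __future__ import annotations

import numpy as np

LABELS: tuple[str, str, str] = ("healthy", "caution", "critical")
LABEL_TO_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(LABELS)}

#: Most-severe-first ordering used for precedence rules and tie-breaks.
SEVERITY_ORDER: tuple[str, str, str] = ("critical", "caution", "healthy")


def severity(label: str) -> int:
    """Severity rank of a label; higher is more severe."""
    return LABEL_TO_INDEX[label]


def check_label(label: str) -> str:
    if label not in LABEL_TO_INDEX:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    return label


def severe_argmax(rows: np.ndarray) -> np.ndarray:
    """Row-wise argmax over class probabilities, ties going to the more
    severe class.

    Parameters
    ----------
    rows:
        Array of shape ``(n, 3)`` (or ``(3,)``) in :data:`LABELS` column
        order.

    Returns
    -------
    Integer label indices, shape ``(n,)``.
    """
    rows = np.atleast_2d(np.asarray(rows))
    # argmax on the reversed columns returns the *last* maximal column of
    # the original, i.e. the most severe one.
    return rows.shape[1] - 1 - np.argmax(rows[:, ::-1], axis=1)
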