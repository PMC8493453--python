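"""Core document type and JSON Lines serialization.

A :class:`LabeledDocument` is one examination record: the individual
diagnosis text, the categorical hormone-examination status, an optional
comprehensive report, and the gold triage label.  The model input is the
*assembled* text: diagnosis, then the hormone status rendered as a fixed
canonical sentence, then the comprehensive report (when present), in that
order.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

from .labels import check_label

HORMONE_STATUSES = ("normal", "abnormal", "not_conducted")

#: Canonical textualization of the three hormone-examination categories.
HORMONE_SENTENCES = {
    "normal": "hormone examination results were normal.",
    "abnormal": "hormone examination results were abnormal.",
    "not_conducted": "hormone examination was not conducted.",
}


def hormone_to_sentence(status: str) -> str:
    """Render a hormone-examination status category as its canonical sentence.

    Raises
    ------
    ValueError
        If ``status`` is not one of ``normal``, ``abnormal``,
        ``not_conducted``.
    """
    try:
        return HORMONE_SENTENCES[status]
    except KeyError:
        raise ValueError(
            f"unknown hormone status {status!r}; expected one of {HORMONE_STATUSES}"
        ) from None


@dataclass
class LabeledDocument:
    doc_id: str
    diagnosis: str
    hormone_status: str
    comprehensive: str | None
    label: str
    #: doc_id of the source record; augmented prefixes share their source's
    #: lineage and must never cross train/valid/test splits.
    lineage: str = ""
    augmented: bool = False
    #: pre-assembled text override, used by augmentation (sentence prefixes
    #: of the assembled text cut across the three structural fields).
    text: str | None = None

    def __post_init__(self) -> None:
        check_label(self.label)
        if self.text is None and not self.diagnosis:
            raise ValueError(f"document {self.doc_id}: diagnosis must be non-empty")
        if self.hormone_status not in HORMONE_STATUSES:
            raise ValueError(
                f"document {self.doc_id}: bad hormone status {self.hormone_status!r}"
            )
        if not self.lineage:
            self.lineage = self.doc_id

    def full_text(self) -> str:
        """Assembled model input: diagnosis + hormone sentence
        + comprehensive report (or the augmentation override verbatim)."""
        if self.text is not None:
            return self.text
        parts = [self.diagnosis, hormone_to_sentence(self.hormone_status)]
        if self.comprehensive:
            parts.append(self.comprehensive)
        return " ".join(p.strip() for p in parts if p.strip())


def write_jsonl(docs: Iterable[LabeledDocument], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(asdict(doc), ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path) -> list[LabeledDocument]:
    docs = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                docs.append(LabeledDocument(**json.loads(line)))
    return docs


def iter_texts(docs: Iterable[LabeledDocument]) -> Iterator[str]:
    for doc in docs:
        yield doc.full_text()


def phrase_pattern(phrase: str) -> re.Pattern[str]:
    """Compile a case-insensitive, word-boundary-anchored matcher for a
    keyword phrase; interior whitespace/hyphens match interchangeably
    (``fine-needle`` matches ``fine needle``)."""
    words = [re.escape(w) for w in re.split(r"[\s-]+", phrase.strip()) if w]
    return re.compile(r"\b" + r"[\s-]+".join(words) + r"\b", re.IGNORECASE)


def contains_phrase(text: str, phrase: str) -> bool:
    return bool(phrase_pattern(phrase).search(text))
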