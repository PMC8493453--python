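"""Text cleaning, sentence handling, prefix augmentation, trimming and
stratified dataset splitting.

Cleaning keeps letters, digits and a small whitelist of special characters
(units, dates and decimal measurements survive; bracketed clutter does
not).  Cumulative sentence-prefix augmentation expands an n-sentence
training document into its n sentence prefixes, which oversamples the rare
class without inventing text.  Keyword-based trimming cuts a comprehensive
report down to one sentence before the first keyword-bearing sentence
through the end, to respect transformer input-length limits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .documents import LabeledDocument, contains_phrase, hormone_to_sentence  # noqa: F401
from .labels import LABELS

__all__ = [
    "CleaningPolicy",
    "SplitRatios",
    "DatasetSplit",
    "clean_text",
    "hormone_to_sentence",
    "split_sentences",
    "augment_cumulative",
    "stratified_split",
    "balance_train_classes",
    "trim_comprehensive",
    "largest_remainder",
]

#: Special characters retained by default cleaning.
DEFAULT_SPECIALS = "%'/~²-,."


@dataclass(frozen=True)
class CleaningPolicy:
    """Character whitelist: letters of the allowed scripts, digits, a small
    set of special characters, and single spaces."""

    allowed_specials: str = DEFAULT_SPECIALS
    #: keep all unicode word characters instead of Latin letters only
    unicode_letters: bool = False

    def __post_init__(self) -> None:
        if not self.allowed_specials:
            raise ValueError("allowed_specials must be non-empty")

    @property
    def pattern(self) -> re.Pattern[str]:
        specials = re.escape(self.allowed_specials)
        letters = r"\w" if self.unicode_letters else "A-Za-z0-9"
        return re.compile(rf"[^{letters}{specials}\s]+")


DEFAULT_POLICY = CleaningPolicy()


def clean_text(raw: str, policy: CleaningPolicy = DEFAULT_POLICY) -> str:
    """Strip disallowed characters and collapse whitespace; idempotent."""
    out = policy.pattern.sub(" ", raw)
    return re.sub(r"\s+", " ", out).strip()


_TERMINATORS = ".?!"


def split_sentences(text: str) -> list[str]:
    """Split on ``.?!`` followed by whitespace or end of text.

    A period flanked by digits (``2.78``) is never a boundary because it is
    not followed by whitespace.  Joining the result with single spaces
    reproduces the input up to boundary whitespace.
    """
    sentences: list[str] = []
    start = 0
    i = 0
    n = len(text)
    while i < n:
        if text[i] in _TERMINATORS and (i + 1 == n or text[i + 1].isspace()):
            # absorb runs like "?!" or "..."
            while i + 1 < n and text[i + 1] in _TERMINATORS:
                i += 1
            chunk = text[start : i + 1].strip()
            if chunk:
                sentences.append(chunk)
            start = i + 1
        i += 1
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def augment_cumulative(doc: LabeledDocument) -> list[LabeledDocument]:
    """Expand a document into its cumulative sentence prefixes.

    An n-sentence document yields exactly n documents: the k-th holds the
    first k sentences in original order, inherits the source label and
    lineage, and the n-th reproduces the full source text.

    Raises
    ------
    ValueError
        If the document has zero sentences.
    """
    sentences = split_sentences(doc.full_text())
    if not sentences:
        raise ValueError(f"document {doc.doc_id} has no sentences to augment")
    out = []
    for k in range(1, len(sentences) + 1):
        out.append(
            replace(
                doc,
                doc_id=f"{doc.doc_id}#aug{k}",
                lineage=doc.lineage,
                augmented=True,
                text=" ".join(sentences[:k]),
            )
        )
    return out


@dataclass(frozen=True)
class SplitRatios:
    """Train/validation/test fractions; default 7:1:2."""

    train: float = 0.7
    valid: float = 0.1
    test: float = 0.2

    def __post_init__(self) -> None:
        total = self.train + self.valid + self.test
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {total}")
        if min(self.train, self.valid, self.test) <= 0:
            raise ValueError("each split ratio must be > 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.train, self.valid, self.test)


@dataclass
class DatasetSplit:
    train: list[LabeledDocument] = field(default_factory=list)
    valid: list[LabeledDocument] = field(default_factory=list)
    test: list[LabeledDocument] = field(default_factory=list)

    def lineages(self) -> tuple[set[str], set[str], set[str]]:
        return (
            {d.lineage for d in self.train},
            {d.lineage for d in self.valid},
            {d.lineage for d in self.test},
        )


def largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Apportion ``n`` items to ``fractions`` exactly (counts sum to n),
    assigning leftovers by largest fractional part; ties go to the earlier
    bucket.  Reproduces 7/1/2 for n=10 at ratios 0.7/0.1/0.2."""
    raw = [n * f for f in fractions]
    counts = [int(x) for x in raw]
    order = sorted(
        range(len(fractions)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in range(n - sum(counts)):
        counts[order[i % len(order)]] += 1
    return counts


MIN_CLASS_SIZE = 10


def stratified_split(
    corpus: list[LabeledDocument],
    ratios: SplitRatios = SplitRatios(),
    augment_minority: set[str] = frozenset(),
    seed: int = 0,
) -> DatasetSplit:
    """Per-class 7:1:2-style split with train-only prefix augmentation.

    Each class is shuffled and apportioned by largest-remainder rounding;
    classes listed in ``augment_minority`` have their *training* documents
    expanded by :func:`augment_cumulative` (validation and test are never
    augmented).  The training set is then shuffled.  Deterministic under
    ``seed``.

    Raises
    ------
    ValueError
        If any class has fewer than 10 documents (named in the message).
    """
    bad = augment_minority - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels in augment_minority: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[LabeledDocument]] = {lab: [] for lab in LABELS}
    for doc in corpus:
        by_class[doc.label].append(doc)
    split = DatasetSplit()
    for lab in LABELS:
        docs = by_class[lab]
        if len(docs) < MIN_CLASS_SIZE:
            raise ValueError(
                f"class {lab!r} has only {len(docs)} documents; "
                f"need at least {MIN_CLASS_SIZE}"
            )
        perm = rng.permutation(len(docs))
        shuffled = [docs[i] for i in perm]
        n_train, n_valid, n_test = largest_remainder(len(docs), ratios.as_tuple())
        train = shuffled[:n_train]
        if lab in augment_minority:
            train = [aug for doc in train for aug in augment_cumulative(doc)]
        split.train.extend(train)
        split.valid.extend(shuffled[n_train : n_train + n_valid])
        split.test.extend(shuffled[n_train + n_valid :])
    perm = rng.permutation(len(split.train))
    split.train = [split.train[i] for i in perm]
    return split


def balance_train_classes(
    train: list[LabeledDocument], seed: int = 0
) -> list[LabeledDocument]:
    """Equalize training class sizes by downsampling the larger classes to
    the (post-augmentation) minority count, then reshuffle.

    This reproduces the balanced-training condition the classifiers
    assume (the rare class having first been prefix-augmented);
    validation and test sets keep their natural imbalance.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[LabeledDocument]] = {lab: [] for lab in LABELS}
    for doc in train:
        by_class[doc.label].append(doc)
    sizes = {lab: len(d) for lab, d in by_class.items() if d}
    if not sizes:
        return []
    target = min(sizes.values())
    out: list[LabeledDocument] = []
    for lab in LABELS:
        docs = by_class[lab]
        if len(docs) > target:
            keep = rng.choice(len(docs), size=target, replace=False)
            docs = [docs[i] for i in sorted(keep)]
        out.extend(docs)
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]


def trim_comprehensive(report: str, keyword: str) -> str:
    """Keyword-based trimming of a comprehensive report.

    Returns the sentences from ``max(0, i - 1)`` to the end, where ``i`` is
    the index of the first sentence containing ``keyword``; the report
    passes through unchanged when the keyword is absent (or already in the
    first two sentences, where the window covers the whole text).
    """
    if not keyword:
        raise ValueError("keyword must be non-empty")
    sentences = split_sentences(report)
    first = next(
        (i for i, s in enumerate(sentences) if contains_phrase(s, keyword)), None
    )
    if first is None or first <= 1:
        return report
    return " ".join(sentences[first - 1 :])
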