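"""Two-stage tokenization: pluggable word-level pre-segmentation followed
by learned subword segmentation with greedy longest-match-first encoding.

The subword vocabulary is induced WordPiece-style: it starts from the full
character inventory of the corpus (so unknown tokens arise only for unseen
characters) and greedily admits the merged piece with the highest
likelihood-gain score ``count(ab) / (count(a) * count(b))`` — the piece
whose corpus probability most exceeds the product of its parts' — until the
target size is reached.  Encoding decomposes each word into the longest
matching vocabulary prefixes, non-initial pieces carrying the ``##``
continuation marker.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

PAD, UNK, CLS, SEP = "[PAD]", "[UNK]", "[CLS]", "[SEP]"
SPECIALS = (PAD, UNK, CLS, SEP)

_WORD_RE = re.compile(r"\d+(?:\.\d+)*|[^\W\d_]+|[^\w\s]", re.UNICODE)

#: Pluggable morphological pre-segmentation hook.  The default splits on
#: whitespace, punctuation, and letter/digit boundaries while keeping
#: decimal numbers intact; a language-specific morphological analyzer can
#: be dropped in with the same signature.
Presegmenter = Callable[[str], list[str]]


def presegment(text: str) -> list[str]:
    """Default rule-based word segmentation: ``"left nodule 2.78cm"`` →
    ``["left", "nodule", "2.78", "cm"]``.  Deterministic."""
    return _WORD_RE.findall(text)


@dataclass
class Vocabulary:
    """Subword inventory with continuation marker and special tokens."""

    tokens: list[str]
    continuation_marker: str = "##"

    token_to_id: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.token_to_id = {tok: i for i, tok in enumerate(self.tokens)}
        if len(self.token_to_id) != len(self.tokens):
            raise ValueError("vocabulary contains duplicate tokens")
        for sp in SPECIALS:
            if sp not in self.token_to_id:
                raise ValueError(f"special token {sp} missing from vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS]

    @property
    def sep_id(self) -> int:
        return self.token_to_id[SEP]

    def save(self, path: str | Path) -> None:
        """One token per line after a JSON header (size, marker, specials)."""
        header = {
            "size": len(self.tokens),
            "continuation_marker": self.continuation_marker,
            "specials": list(SPECIALS),
        }
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(json.dumps(header) + "\n")
            for tok in self.tokens:
                fh.write(tok + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        with Path(path).open("r", encoding="utf-8") as fh:
            header = json.loads(fh.readline())
            tokens = [line.rstrip("\n") for line in fh]
        tokens = tokens[: header["size"]]
        return cls(tokens=tokens, continuation_marker=header["continuation_marker"])


@dataclass
class TokenSequence:
    ids: list[int]
    truncated: bool = False

    @property
    def length(self) -> int:
        return len(self.ids)


def _word_symbols(word: str, marker: str) -> list[str]:
    return [word[0]] + [marker + ch for ch in word[1:]]


def train_subword_vocab(
    corpus: Iterable[str],
    target_size: int,
    marker: str = "##",
    presegmenter: Presegmenter = presegment,
) -> Vocabulary:
    """Induce a subword vocabulary of at most ``target_size`` tokens.

    Starts from every character seen in the corpus (word-initial form plus
    marked continuation form) and repeatedly admits the adjacent pair with
    the highest likelihood-gain score ``count(pair)/(count(a)·count(b))``;
    ties break lexicographically on the merged token, so induction is
    deterministic given the corpus.

    Raises
    ------
    ValueError
        If ``target_size`` cannot hold the character inventory plus the
        special tokens.
    """
    word_freq: Counter[str] = Counter()
    for text in corpus:
        word_freq.update(presegmenter(text))
    if not word_freq:
        raise ValueError("empty corpus")
    words = {w: _word_symbols(w, marker) for w in word_freq}
    alphabet = sorted({sym for syms in words.values() for sym in syms})
    floor = len(alphabet) + len(SPECIALS)
    if target_size < floor:
        raise ValueError(
            f"target_size {target_size} below character inventory + specials ({floor})"
        )
    vocab_tokens = list(SPECIALS) + alphabet
    while len(vocab_tokens) < target_size:
        pair_counts: Counter[tuple[str, str]] = Counter()
        sym_counts: Counter[str] = Counter()
        for w, syms in words.items():
            f = word_freq[w]
            for sym in syms:
                sym_counts[sym] += f
            for a, b in zip(syms, syms[1:]):
                pair_counts[(a, b)] += f
        if not pair_counts:
            break
        def merged(pair: tuple[str, str]) -> str:
            a, b = pair
            return a + (b[len(marker):] if b.startswith(marker) else b)
        # highest likelihood gain first; ties broken lexicographically on
        # the merged token
        best = min(
            pair_counts,
            key=lambda p: (
                -pair_counts[p] / (sym_counts[p[0]] * sym_counts[p[1]]),
                merged(p),
            ),
        )
        new_tok = merged(best)
        if new_tok in vocab_tokens:
            # already admitted through another path; merge occurrences only
            pass
        else:
            vocab_tokens.append(new_tok)
        a, b = best
        for w, syms in words.items():
            out: list[str] = []
            i = 0
            while i < len(syms):
                if i + 1 < len(syms) and syms[i] == a and syms[i + 1] == b:
                    out.append(new_tok)
                    i += 2
                else:
                    out.append(syms[i])
                    i += 1
            words[w] = out
    return Vocabulary(tokens=vocab_tokens, continuation_marker=marker)


def encode(
    text: str,
    vocab: Vocabulary,
    max_len: int = 512,
    add_specials: bool = True,
    presegmenter: Presegmenter = presegment,
) -> TokenSequence:
    """Greedy longest-match-first subword encoding.

    Each pre-segmented word is decomposed into the longest vocabulary
    prefixes; non-initial pieces carry the continuation marker; characters
    absent from the vocabulary map to ``[UNK]``.  With ``add_specials`` the
    sequence is framed as ``[CLS] … [SEP]``.  Sequences longer than
    ``max_len`` are truncated (keeping the trailing ``[SEP]``) and flagged.
    """
    if add_specials and max_len < 3:
        raise ValueError("max_len must be >= 3 when adding CLS/SEP")
    if max_len < 1:
        raise ValueError("max_len must be positive")
    marker = vocab.continuation_marker
    ids: list[int] = []
    for word in presegmenter(text):
        pos = 0
        while pos < len(word):
            piece_id = None
            for end in range(len(word), pos, -1):
                cand = word[pos:end]
                if pos > 0:
                    cand = marker + cand
                if cand in vocab:
                    piece_id = vocab.token_to_id[cand]
                    pos = end
                    break
            if piece_id is None:
                piece_id = vocab.unk_id
                pos += 1
            ids.append(piece_id)
    if add_specials:
        ids = [vocab.cls_id] + ids + [vocab.sep_id]
    truncated = len(ids) > max_len
    if truncated:
        ids = ids[: max_len - 1] + [vocab.sep_id] if add_specials else ids[:max_len]
    return TokenSequence(ids=ids, truncated=truncated)


def decode(seq: TokenSequence | Sequence[int], vocab: Vocabulary) -> str:
    """Invert :func:`encode`: strip specials, glue continuation pieces.

    Round-trips any text of space-separated in-vocabulary words.
    """
    ids = seq.ids if isinstance(seq, TokenSequence) else list(seq)
    marker = vocab.continuation_marker
    words: list[str] = []
    for i in ids:
        if not 0 <= i < len(vocab):
            raise ValueError(f"token id {i} out of range for vocabulary")
        tok = vocab.tokens[i]
        if tok in SPECIALS:
            continue
        if tok.startswith(marker) and words:
            words[-1] += tok[len(marker):]
        else:
            words.append(tok)
    return " ".join(words)


#: canonical stand-in for numeric tokens in the word-level route — raw
#: measurements are near-unique strings, so mapping them to one token keeps
#: them out of the OOV bucket
NUM = "[NUM]"

_NUMERIC_RE = re.compile(r"^\d+(?:\.\d+)*$")


def canonicalize_word(word: str) -> str:
    return NUM if _NUMERIC_RE.match(word) else word


def build_word_vocab(
    corpus: Iterable[str], presegmenter: Presegmenter = presegment
) -> tuple[list[str], dict[str, int]]:
    """Word-level vocabulary (frequency-sorted, then lexicographic) with
    ``[PAD]``/``[UNK]`` first and numbers canonicalized — used by the
    word-token CNN/LSTM route."""
    freq: Counter[str] = Counter()
    for text in corpus:
        freq.update(canonicalize_word(w) for w in presegmenter(text))
    words = [PAD, UNK] + sorted(freq, key=lambda w: (-freq[w], w))
    return words, {w: i for i, w in enumerate(words)}


def encode_words(
    text: str,
    word_to_id: dict[str, int],
    max_len: int = 2240,
    presegmenter: Presegmenter = presegment,
) -> TokenSequence:
    """Word-level encoding for the CNN/LSTM route (no specials)."""
    unk = word_to_id[UNK]
    ids = [
        word_to_id.get(canonicalize_word(w), unk) for w in presegmenter(text)
    ]
    truncated = len(ids) > max_len
    return TokenSequence(ids=ids[:max_len], truncated=truncated)
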