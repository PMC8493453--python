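"""Synthetic labeled report generator.

Emulates the statistical and structural properties of free-text thyroid
examination records so the whole pipeline is testable without any private
clinical data: a three-part document (individual diagnosis, hormone status,
optional comprehensive report), class-discriminative ultrasonography
keywords with severity precedence, severe class imbalance
(~68.6 / 30.4 / 1.0 %), a mix of complete sentences and enumerated keyword
phrases, and light typographical noise.

Labels follow a keyword rule: a document receives the most severe class
whose keyword set matches its text; documents with no keyword default to
healthy (dominant in real screening data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .documents import LabeledDocument, contains_phrase, hormone_to_sentence
from .labels import LABELS, SEVERITY_ORDER


@dataclass(frozen=True)
class KeywordRuleSet:
    """Keyword lists defining the three triage classes.

    The default rule set is the thyroid-ultrasonography criterion:
    benign/normal findings are healthy; structural findings that warrant
    follow-up are caution; findings suggesting malignancy work-up are
    critical.  The three sets must be pairwise disjoint; multi-keyword
    documents resolve by severity precedence (critical > caution > healthy).
    """

    healthy_keywords: frozenset[str]
    caution_keywords: frozenset[str]
    critical_keywords: frozenset[str]
    severity_order: tuple[str, str, str] = SEVERITY_ORDER

    def __post_init__(self) -> None:
        sets = [self.healthy_keywords, self.caution_keywords, self.critical_keywords]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(f"keyword sets overlap: {sorted(overlap)}")
        if sorted(self.severity_order) != sorted(LABELS):
            raise ValueError("severity_order must be a permutation of the labels")

    def keywords_for(self, label: str) -> frozenset[str]:
        return {
            "healthy": self.healthy_keywords,
            "caution": self.caution_keywords,
            "critical": self.critical_keywords,
        }[label]


DEFAULT_RULES = KeywordRuleSet(
    healthy_keywords=frozenset(
        {
            "no abnormalities",
            "normal",
            "simple cyst",
            "tubular cyst",
            "thyroid resection",
            "thyroidectomy",
            "benign calcification",
        }
    ),
    caution_keywords=frozenset(
        {
            "hypothyroidism",
            "unequal parenchyma",
            "internal thyroid disease",
            "thyroiditis",
            "nodule",
            "thyromegaly",
            "hyperechoic lesion",
            "hypoechoic lesion",
            "hyperechoic nodules",
            "hypoechoic nodules",
            "cystic lesions",
        }
    ),
    critical_keywords=frozenset(
        {
            "tumor",
            "malignant",
            "biopsy",
            "fine needle aspiration cytology",
        }
    ),
)


def keyword_label(doc_text: str, rules: KeywordRuleSet = DEFAULT_RULES) -> str:
    """Label a text by its most severe matching keyword set.

    Total on text: returns ``healthy`` when no keyword matches.
    Matching is case-insensitive, word-boundary anchored, and treats
    hyphens and spaces inside a phrase interchangeably.
    """
    for label in rules.severity_order:
        if any(contains_phrase(doc_text, kw) for kw in rules.keywords_for(label)):
            return label
    return "healthy"


@dataclass
class CorpusConfig:
    """Generation parameters.

    Defaults reproduce the emulated screening-population conditions: class proportions
    68.6 / 30.4 / 1.0 % (healthy / caution / critical), occasional missing
    comprehensive sections, a mix of sentence-style and enumerated
    comprehensive reports, and a small typo/space-perturbation rate.
    """

    n_documents: int = 1000
    class_proportions: tuple[float, float, float] = (0.686, 0.304, 0.010)
    p_missing_comprehensive: float = 0.1
    p_enumerated_style: float = 0.3
    sentence_count_range: tuple[int, int] = (2, 6)
    noise_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_documents < 1:
            raise ValueError("n_documents must be positive")
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (3,):
            raise ValueError("class_proportions must have 3 entries")
        if not math.isclose(float(p.sum()), 1.0, abs_tol=1e-9):
            raise ValueError(f"class_proportions must sum to 1, got {p.sum()!r}")
        if np.any(p <= 0):
            raise ValueError("every class proportion must be > 0")
        for name in ("p_missing_comprehensive", "p_enumerated_style", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.sentence_count_range
        if not (1 <= lo <= hi):
            raise ValueError("sentence_count_range must be a valid interval >= 1")


# ----------------------------------------------------------------- templates

# Diagnosis templates always embed the class keyword, so every sentence
# prefix of the assembled document still carries the class signal.
_DIAGNOSIS_TEMPLATES = {
    "healthy": (
        "thyroid ultrasonography reads {kw}.",
        "thyroid study shows {kw} without further findings.",
        "{kw} on thyroid screening.",
    ),
    "caution": (
        "thyroid ultrasonography shows {kw} on the left lobe.",
        "thyroid study reveals {kw} measuring {size} cm.",
        "{kw} observed in the right thyroid lobe.",
    ),
    "critical": (
        "findings suspicious for {kw}; specialist review advised.",
        "we recommend taking a {kw} for the {size} cm finding.",
        "{kw} result requires urgent follow up.",
    ),
}

# Keyword-free comprehensive filler phrases (no triage keyword of any class
# may appear here, so they never override the diagnosis label).
_FILLERS = (
    "total cholesterol level is high",
    "please be aware of weight management",
    "neutral fat level is high",
    "low density lipoprotein cholesterol level is high",
    "blood pressure within reference range",
    "uibc decreases and iron increases",
    "glucose increases on fasting test",
    "osteoporosis risk noted on bone density",
    "hepatitis b antibody not formed",
    "dense breast on both sides",
    "gallstone and cholesterol polyps",
    "gastritis on upper gastrointestinography",
    "cervicitis follow up recommended",
    "no antibody for hepatitis a",
    "renal function test unremarkable",
    "liver enzyme slightly elevated",
    "body mass index above reference",
    "upper gastrointestinography results reviewed",
)

# Label-echo phrases reusable inside comprehensive reports (own class only).
_ECHO = {
    "healthy": ("{kw} impression maintained",),
    "caution": ("{kw} to be rechecked in twelve months",),
    "critical": ("confirm with {kw} and consult the doctor",),
}

_ALPHA = "abcdefghijklmnopqrstuvwxyz"


def _size(rng: np.random.Generator) -> str:
    return f"{rng.integers(1, 40) / 10 + rng.integers(0, 10) / 100:.2f}"


def _perturb_word(word: str, rng: np.random.Generator) -> str:
    """One random typo: character substitution or deletion."""
    if len(word) < 2:
        return word
    i = int(rng.integers(0, len(word)))
    if rng.random() < 0.5:
        return word[:i] + _ALPHA[int(rng.integers(0, 26))] + word[i + 1 :]
    return word[:i] + word[i + 1 :]


def _noisy_sentence(sentence: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return sentence
    words = sentence.split(" ")
    out: list[str] = []
    for w in words:
        if rng.random() < rate:
            w = _perturb_word(w, rng)
        # occasional word-space deletion, emulating spacing inconsistency
        if out and rng.random() < rate / 2:
            out[-1] = out[-1] + w
        else:
            out.append(w)
    return " ".join(out)


def _comprehensive(
    label: str,
    rules: KeywordRuleSet,
    config: CorpusConfig,
    rng: np.random.Generator,
) -> str | None:
    if rng.random() < config.p_missing_comprehensive:
        return None
    lo, hi = config.sentence_count_range
    n_items = int(rng.integers(lo, hi + 1))
    items: list[str] = []
    for _ in range(n_items):
        if rng.random() < 0.25:
            tmpl = _ECHO[label][int(rng.integers(0, len(_ECHO[label])))]
            kw = sorted(rules.keywords_for(label))[
                int(rng.integers(0, len(rules.keywords_for(label))))
            ]
            items.append(tmpl.format(kw=kw))
        else:
            filler = _FILLERS[int(rng.integers(0, len(_FILLERS)))]
            items.append(_noisy_sentence(filler, config.noise_rate, rng))
    if rng.random() < config.p_enumerated_style:
        return " ".join(f"{i + 1}. {item}" for i, item in enumerate(items)) + "."
    return " ".join(item + "." for item in items)


def _diagnosis(label: str, rules: KeywordRuleSet, rng: np.random.Generator) -> str:
    templates = _DIAGNOSIS_TEMPLATES[label]
    tmpl = templates[int(rng.integers(0, len(templates)))]
    kws = sorted(rules.keywords_for(label))
    kw = kws[int(rng.integers(0, len(kws)))]
    text = tmpl.format(kw=kw, size=_size(rng))
    if label == "critical" and rng.random() < 0.5:
        # critical reports often also mention a less severe finding; it
        # follows the critical sentence so every augmentation prefix keeps
        # the class keyword
        text = text + f" thyroid ultrasonography shows {_size(rng)} cm of left nodule."
    return text


def generate_corpus(
    config: CorpusConfig, rules: KeywordRuleSet = DEFAULT_RULES
) -> list[LabeledDocument]:
    """Generate a labeled synthetic corpus.

    Every document's assembled text contains at least one keyword of its
    gold label's set and no keyword of a strictly more severe set, so
    :func:`keyword_label` recovers the gold label exactly.  Byte-identical
    output under equal seeds.

    Raises
    ------
    ValueError
        On invalid configuration, or when ``n_documents`` is so small that
        a class receives zero documents (the error names the class).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    label_idx = rng.choice(3, size=config.n_documents, p=config.class_proportions)
    counts = np.bincount(label_idx, minlength=3)
    for lab, c in zip(LABELS, counts):
        if c == 0:
            raise ValueError(
                f"class {lab!r} received zero documents; increase n_documents"
            )
    docs: list[LabeledDocument] = []
    width = len(str(config.n_documents))
    for i, li in enumerate(label_idx):
        label = LABELS[int(li)]
        hormone = ("normal", "abnormal", "not_conducted")[
            int(rng.choice(3, p=(0.6, 0.25, 0.15)))
        ]
        for _attempt in range(8):
            diagnosis = _diagnosis(label, rules, rng)
            comprehensive = _comprehensive(label, rules, config, rng)
            doc = LabeledDocument(
                doc_id=f"doc-{i:0{width}d}",
                diagnosis=diagnosis,
                hormone_status=hormone,
                comprehensive=comprehensive,
                label=label,
            )
            if keyword_label(doc.full_text(), rules) == label:
                break
        else:  # pragma: no cover - noise never fabricates multi-word keywords
            raise RuntimeError(f"could not realize label {label} for doc {i}")
        docs.append(doc)
    return docs
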