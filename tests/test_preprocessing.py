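"""Cleaning, sentence splitting, prefix augmentation, trimming and
stratified splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scentnlp.documents import LabeledDocument, hormone_to_sentence
from scentnlp.preprocessing import (
    CleaningPolicy,
    SplitRatios,
    augment_cumulative,
    balance_train_classes,
    clean_text,
    largest_remainder,
    split_sentences,
    stratified_split,
    trim_comprehensive,
)


class TestCleanText:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("renal cyst (left side 1.4 cm)", "renal cyst left side 1.4 cm"),
            ("", ""),
            ("a@#$b", "a b"),
            ("blood pressure 120/80 mm/Hg", "blood pressure 120/80 mm/Hg"),
            ("x  \t y", "x y"),
            ("95% ok ~2cm", "95% ok ~2cm"),
        ],
    )
    def test_whitelist(self, raw, expected):
        assert clean_text(raw) == expected

    @given(st.text(max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_idempotent_and_closed(self, raw):
        once = clean_text(raw)
        assert clean_text(once) == once
        allowed = set("%'/~²-,. ")
        for ch in once:
            assert ch.isascii() and ch.isalnum() or ch in allowed, ch

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValueError):
            CleaningPolicy(allowed_specials="")


class TestHormoneSentences:
    @pytest.mark.parametrize(
        "status,expected",
        [
            ("normal", "hormone examination results were normal."),
            ("abnormal", "hormone examination results were abnormal."),
            ("not_conducted", "hormone examination was not conducted."),
        ],
    )
    def test_canonical_sentences(self, status, expected):
        assert hormone_to_sentence(status) == expected

    def test_unknown_status(self):
        with pytest.raises(ValueError, match="banana"):
            hormone_to_sentence("banana")


class TestSplitSentences:
    def test_decimal_point_never_splits(self):
        out = split_sentences("A is fine. B is 2.78 cm. See doctor.")
        assert len(out) == 3
        assert "2.78 cm" in out[1]

    @pytest.mark.parametrize("text,n", [("one sentence", 1), ("", 0), ("Go! Now? Yes.", 3)])
    def test_counts(self, text, n):
        assert len(split_sentences(text)) == n

    @given(
        st.lists(
            st.text(alphabet="abc 2.7", min_size=1, max_size=12).map(
                lambda s: s.strip() or "a"
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_join_reproduces_input_up_to_whitespace(self, chunks):
        text = ". ".join(chunks) + "."
        joined = " ".join(split_sentences(text))
        assert " ".join(joined.split()) == " ".join(text.split())


def _doc(diagnosis, comprehensive=None, label="healthy", doc_id="d0"):
    return LabeledDocument(
        doc_id=doc_id, diagnosis=diagnosis, hormone_status="normal",
        comprehensive=comprehensive, label=label,
    )


class TestAugmentCumulative:
    def test_three_sentence_document_yields_three_prefixes(self):
        # diagnosis + hormone sentence + comprehensive = 3 sentences
        doc = _doc("First thing noted.", comprehensive="Third item.")
        out = augment_cumulative(doc)
        sentences = split_sentences(doc.full_text())
        assert len(out) == len(sentences) == 3
        for k, aug in enumerate(out, start=1):
            assert aug.full_text() == " ".join(sentences[:k])
            assert aug.label == doc.label
            assert aug.lineage == doc.doc_id
        assert out[-1].full_text() == " ".join(sentences)

    def test_single_sentence_document_is_itself(self):
        doc = LabeledDocument(
            doc_id="d", diagnosis="only sentence", hormone_status="normal",
            comprehensive=None, label="healthy", text="only sentence",
        )
        out = augment_cumulative(doc)
        assert len(out) == 1
        assert out[0].full_text() == "only sentence"

    def test_each_prefix_is_strict_prefix_of_next(self):
        doc = _doc("S1 a.", comprehensive="S3 c. S4 d. S5 e.")
        out = augment_cumulative(doc)
        assert len(out) == 5
        for a, b in zip(out, out[1:]):
            assert b.full_text().startswith(a.full_text())
            assert len(b.full_text()) > len(a.full_text())

    def test_augmentation_count_matches_sentence_count(self, small_corpus):
        for doc in small_corpus[:50]:
            n = len(split_sentences(doc.full_text()))
            assert len(augment_cumulative(doc)) == n

    def test_zero_sentences_rejected(self):
        doc = LabeledDocument(
            doc_id="d", diagnosis="x", hormone_status="normal",
            comprehensive=None, label="healthy", text="   ",
        )
        with pytest.raises(ValueError, match="no sentences"):
            augment_cumulative(doc)


class TestTrimComprehensive:
    def test_keyword_in_third_sentence_keeps_from_second(self):
        report = "S0 a. S1 b. S2 thyroid here. S3 c. S4 d. S5 e."
        out = trim_comprehensive(report, "thyroid")
        assert out == "S1 b. S2 thyroid here. S3 c. S4 d. S5 e."

    def test_keyword_absent_passes_through(self):
        report = "S0 a. S1 b. S2 c."
        assert trim_comprehensive(report, "thyroid") == report

    def test_keyword_in_first_sentence_unchanged(self):
        report = "thyroid first. S1 b. S2 c."
        assert trim_comprehensive(report, "thyroid") == report

    def test_randomized_reports_window_rule(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            kw_at = int(rng.integers(0, n))
            sentences = [
                ("thyroid noted here." if i == kw_at else f"finding number {i} listed.")
                for i in range(n)
            ]
            report = " ".join(sentences)
            out = trim_comprehensive(report, "thyroid")
            expected = (
                report if kw_at <= 1 else " ".join(sentences[kw_at - 1 :])
            )
            assert out == expected
            assert len(out) <= len(report)

    def test_empty_keyword_rejected(self):
        with pytest.raises(ValueError):
            trim_comprehensive("text.", "")


class TestStratifiedSplit:
    def test_largest_remainder_reproduces_7_1_2(self):
        assert largest_remainder(10, (0.7, 0.1, 0.2)) == [7, 1, 2]
        assert largest_remainder(0, (0.7, 0.1, 0.2)) == [0, 0, 0]
        for n in (11, 23, 97):
            counts = largest_remainder(n, (0.7, 0.1, 0.2))
            assert sum(counts) == n

    def test_per_class_counts_and_lineage_partition(self, small_corpus):
        split = stratified_split(small_corpus, SplitRatios(), {"critical"}, seed=5)
        train_l, valid_l, test_l = split.lineages()
        assert not (train_l & valid_l) and not (train_l & test_l) and not (valid_l & test_l)
        assert train_l | valid_l | test_l == {d.doc_id for d in small_corpus}
        # only critical training docs are augmented
        assert all(d.label == "critical" for d in split.train if d.augmented)
        assert not any(d.augmented for d in split.valid + split.test)
        by_class = {lab: 0 for lab in ("healthy", "caution", "critical")}
        for d in small_corpus:
            by_class[d.label] += 1
        for lab, total in by_class.items():
            n_test = sum(d.label == lab for d in split.test)
            assert n_test == largest_remainder(total, (0.7, 0.1, 0.2))[2]

    def test_no_augmentation_preserves_counts(self, small_corpus):
        split = stratified_split(small_corpus, SplitRatios(), set(), seed=5)
        assert len(split.train) + len(split.valid) + len(split.test) == len(small_corpus)

    def test_deterministic_under_seed(self, small_corpus):
        a = stratified_split(small_corpus, SplitRatios(), {"critical"}, seed=9)
        b = stratified_split(small_corpus, SplitRatios(), {"critical"}, seed=9)
        assert [d.doc_id for d in a.train] == [d.doc_id for d in b.train]
        assert [d.doc_id for d in a.test] == [d.doc_id for d in b.test]

    def test_small_class_rejected_by_name(self):
        docs = [
            _doc("normal reading.", label="healthy", doc_id=f"h{i}") for i in range(20)
        ] + [
            _doc("nodule found.", label="caution", doc_id=f"c{i}") for i in range(3)
        ]
        docs += [_doc("tumor found.", label="critical", doc_id=f"x{i}") for i in range(12)]
        with pytest.raises(ValueError, match="caution"):
            stratified_split(docs, SplitRatios(), set(), seed=0)

    def test_ratio_validation(self):
        with pytest.raises(ValueError):
            SplitRatios(0.5, 0.2, 0.2)


class TestBalanceTrain:
    def test_downsamples_to_minority(self, small_corpus):
        split = stratified_split(small_corpus, SplitRatios(), {"critical"}, seed=2)
        balanced = balance_train_classes(split.train, seed=2)
        counts = {}
        for d in balanced:
            counts[d.label] = counts.get(d.label, 0) + 1
        assert len(set(counts.values())) == 1
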