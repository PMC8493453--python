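"""End-to-end experiment orchestration.

A run directory holds every artifact of one experiment: the generated
corpus, split manifests, trained embeddings, the subword vocabulary,
per-member probability matrices, ensemble matrices, final triage labels
and evaluation reports, plus a manifest with a content hash for each file.
Stages skip themselves when their outputs already exist (so deleting just
the evaluation report and re-running regenerates it from the persisted
matrices without retraining).

Two named scale profiles exist: ``desk`` (small models, minutes on one
CPU) and ``paper`` (the full-scale reference hyperparameters; GPU-scale, kept for
reference).  The master seed fans out deterministically to the corpus,
embedding training and ensemble members (member i trains with seed
``master + i``).
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classifiers as clf
from .documents import LabeledDocument, read_jsonl, write_jsonl
from .embeddings import EmbeddingMatrix, SGNSConfig, train_sgns
from .ensemble import scent_v1, scent_v2, soft_vote
from .evaluation import evaluation_report, format_report
from .labels import LABEL_TO_INDEX, LABELS
from .preprocessing import (
    SplitRatios,
    balance_train_classes,
    clean_text,
    stratified_split,
    trim_comprehensive,
)
from .synthetic_corpus import CorpusConfig, generate_corpus
from .tokenization import (
    Vocabulary,
    build_word_vocab,
    canonicalize_word,
    encode,
    encode_words,
    presegment,
    train_subword_vocab,
)

log = logging.getLogger("scentnlp")

ARCHITECTURES = ("cnn", "lstm", "transformer")


@dataclass
class ExperimentConfig:
    profile: str = "desk"
    master_seed: int = 0
    members: int = 3
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    ratios: SplitRatios = field(default_factory=SplitRatios)
    augment_minority: tuple[str, ...] = ("critical",)
    balance_train: bool = True
    trim_keyword: str = "thyroid"
    subword_vocab_size: int = 400
    sgns: SGNSConfig = field(default_factory=SGNSConfig)
    cnn: clf.CNNConfig = field(default_factory=clf.CNNConfig)
    lstm: clf.LSTMConfig = field(default_factory=clf.LSTMConfig)
    transformer: clf.TransformerConfig = field(default_factory=clf.TransformerConfig)
    train_cnn: clf.TrainConfig = field(default_factory=clf.TrainConfig)
    train_lstm: clf.TrainConfig = field(default_factory=clf.TrainConfig)
    train_transformer: clf.TrainConfig = field(default_factory=clf.TrainConfig)

    def validate(self) -> None:
        if self.members < 1:
            raise ValueError("members must be >= 1")
        self.corpus.validate()
        bad = set(self.augment_minority) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels in augment_minority: {sorted(bad)}")
        for cfg in (self.cnn, self.lstm, self.transformer):
            cfg.validate()
        for tc in (self.train_cnn, self.train_lstm, self.train_transformer):
            tc.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        casts = {
            "corpus": CorpusConfig,
            "ratios": SplitRatios,
            "sgns": SGNSConfig,
            "cnn": clf.CNNConfig,
            "lstm": clf.LSTMConfig,
            "transformer": clf.TransformerConfig,
            "train_cnn": clf.TrainConfig,
            "train_lstm": clf.TrainConfig,
            "train_transformer": clf.TrainConfig,
        }
        for key, typ in casts.items():
            if key in data and isinstance(data[key], dict):
                data[key] = typ(**data[key])
        for key in ("augment_minority",):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        for key in ("class_proportions", "sentence_count_range"):
            if isinstance(data.get("corpus"), CorpusConfig):
                val = getattr(data["corpus"], key)
                if isinstance(val, list):
                    setattr(data["corpus"], key, tuple(val))
        if isinstance(data.get("lstm"), clf.LSTMConfig) and isinstance(
            data["lstm"].shortcuts, list
        ):
            data["lstm"].shortcuts = tuple(tuple(s) for s in data["lstm"].shortcuts)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def desk_profile(seed: int = 0, n_documents: int = 2000, members: int = 3) -> ExperimentConfig:
    """Desk-scale profile: small models trainable in minutes on one CPU
    while keeping every structural element of the full system."""
    return ExperimentConfig(
        profile="desk",
        master_seed=seed,
        members=members,
        corpus=CorpusConfig(n_documents=n_documents, seed=seed),
        subword_vocab_size=400,
        sgns=SGNSConfig(dimension=64, context_size=5, negatives=5, epochs=3, seed=seed),
        cnn=clf.CNNConfig(channels=32, block_repeats=2, dropout=0.5, max_len=128),
        lstm=clf.LSTMConfig(
            layers=2, units=64, shortcuts=(), dropout=0.2, max_len=128
        ),
        transformer=clf.TransformerConfig(
            layers=2, heads=2, dim=64, d_ff=128, dropout=0.1, max_len=128
        ),
        train_cnn=clf.TrainConfig(
            epochs=60, batch_size=16, learning_rate=1e-3, patience=3
        ),
        train_lstm=clf.TrainConfig(
            epochs=30, batch_size=16, learning_rate=2e-3, patience=3
        ),
        train_transformer=clf.TrainConfig(
            epochs=40, batch_size=16, learning_rate=5e-4, decay_factor=None
        ),
    )


def paper_profile(seed: int = 0) -> ExperimentConfig:
    """The full-scale reference hyperparameters (GPU-scale; not intended for desk
    runs): 10 members per ensemble, CNN 250 channels x 6 blocks,
    5-layer LSTM with 650 units and (1,3)/(3,5) shortcuts, 12-layer
    12-head transformer with d=768, batch sizes 64/32/8 and initial
    learning rates 1e-3 / 2e-4 / 2e-5."""
    return ExperimentConfig(
        profile="paper",
        master_seed=seed,
        members=10,
        corpus=CorpusConfig(n_documents=122581, seed=seed),
        subword_vocab_size=35000,
        sgns=SGNSConfig(dimension=300, context_size=5, negatives=5, epochs=3, seed=seed),
        cnn=clf.CNNConfig(channels=250, block_repeats=6, dropout=0.5, max_len=2240),
        lstm=clf.LSTMConfig(
            layers=5, units=650, shortcuts=((1, 3), (3, 5)), dropout=0.5, max_len=2240
        ),
        transformer=clf.TransformerConfig(
            layers=12, heads=12, dim=768, d_ff=3072, max_len=512
        ),
        train_cnn=clf.TrainConfig(epochs=30, batch_size=64, learning_rate=1e-3),
        train_lstm=clf.TrainConfig(epochs=30, batch_size=32, learning_rate=2e-4),
        train_transformer=clf.TrainConfig(
            epochs=15, batch_size=8, learning_rate=2e-5, decay_factor=None
        ),
    )


PROFILES = {"desk": desk_profile, "paper": paper_profile}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_probs_csv(path: Path, doc_ids: list[str], probs: np.ndarray) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["doc_id", "p_healthy", "p_caution", "p_critical"])
        for doc_id, row in zip(doc_ids, probs):
            writer.writerow([doc_id] + [f"{p:.8f}" for p in row])


def _read_probs_csv(path: Path) -> tuple[list[str], np.ndarray]:
    with path.open("r", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader)
        ids, rows = [], []
        for rec in reader:
            ids.append(rec[0])
            rows.append([float(x) for x in rec[1:4]])
    return ids, np.asarray(rows)


def _write_labels_csv(path: Path, doc_ids: list[str], labels: list[str]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["doc_id", "label"])
        writer.writerows(zip(doc_ids, labels))


class ExperimentRunner:
    """Stage-by-stage executor over a run directory."""

    def __init__(self, config: ExperimentConfig, run_dir: str | Path, resume: bool = True):
        config.validate()
        self.config = config
        self.run_dir = Path(run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.resume = resume
        self._check_config_consistency()

    # ----------------------------------------------------------- utilities
    def _check_config_consistency(self) -> None:
        cfg_path = self.run_dir / "config.yaml"
        if cfg_path.exists():
            existing = yaml.safe_load(cfg_path.read_text(encoding="utf-8"))
            # JSON round-trip normalizes tuples to lists for comparison
            ours = json.loads(json.dumps(self.config.to_dict()))
            if existing != ours:
                raise ValueError(
                    f"run directory {self.run_dir} was created with a different "
                    "configuration; use a fresh directory"
                )
        else:
            self.config.to_yaml(cfg_path)

    def _path(self, name: str) -> Path:
        return self.run_dir / name

    def _done(self, *names: str) -> bool:
        return self.resume and all(self._path(n).exists() for n in names)

    def _update_manifest(self) -> None:
        manifest = {
            "master_seed": self.config.master_seed,
            "profile": self.config.profile,
            "config_sha256": hashlib.sha256(
                json.dumps(self.config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "artifacts": {},
        }
        for path in sorted(self.run_dir.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                manifest["artifacts"][str(path.relative_to(self.run_dir))] = _sha256(path)
        with self._path("manifest.json").open("w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)

    # -------------------------------------------------------------- stages
    def generate(self) -> list[LabeledDocument]:
        path = self._path("corpus.jsonl")
        if self._done("corpus.jsonl"):
            return read_jsonl(path)
        log.info("generating corpus (%d documents)", self.config.corpus.n_documents)
        docs = generate_corpus(self.config.corpus)
        write_jsonl(docs, path)
        return docs

    def split(self) -> dict[str, list[LabeledDocument]]:
        names = ["train.jsonl", "valid.jsonl", "test.jsonl", "train_balanced.jsonl"]
        if self._done(*names):
            return {n.split(".")[0]: read_jsonl(self._path(n)) for n in names}
        docs = self.generate()
        split = stratified_split(
            docs,
            self.config.ratios,
            set(self.config.augment_minority),
            seed=self.config.master_seed,
        )
        balanced = (
            balance_train_classes(split.train, seed=self.config.master_seed)
            if self.config.balance_train
            else split.train
        )
        write_jsonl(split.train, self._path("train.jsonl"))
        write_jsonl(split.valid, self._path("valid.jsonl"))
        write_jsonl(split.test, self._path("test.jsonl"))
        write_jsonl(balanced, self._path("train_balanced.jsonl"))
        with self._path("split_counts.tsv").open("w", encoding="utf-8") as fh:
            fh.write("split\t" + "\t".join(LABELS) + "\ttotal\n")
            for name, part in [
                ("train", split.train),
                ("train_balanced", balanced),
                ("valid", split.valid),
                ("test", split.test),
            ]:
                counts = [sum(d.label == lab for d in part) for lab in LABELS]
                fh.write(name + "\t" + "\t".join(map(str, counts)) + f"\t{len(part)}\n")
        log.info(
            "split sizes: train=%d (balanced %d) valid=%d test=%d",
            len(split.train), len(balanced), len(split.valid), len(split.test),
        )
        return {
            "train": split.train,
            "valid": split.valid,
            "test": split.test,
            "train_balanced": balanced,
        }

    def train_embeddings(self) -> EmbeddingMatrix:
        path = self._path("embeddings.w2v")
        if self._done("embeddings.w2v"):
            return EmbeddingMatrix.load(path)
        docs = self.generate()
        log.info("training SGNS embeddings (d=%d)", self.config.sgns.dimension)
        stream = [
            [canonicalize_word(w) for w in presegment(clean_text(d.full_text()))]
            for d in docs
        ]
        emb = train_sgns(stream, self.config.sgns)
        emb.save(path)
        return emb

    def subword_vocab(self) -> Vocabulary:
        path = self._path("subword_vocab.txt")
        if self._done("subword_vocab.txt"):
            return Vocabulary.load(path)
        docs = self.generate()
        log.info("inducing subword vocabulary (target %d)", self.config.subword_vocab_size)
        vocab = train_subword_vocab(
            (clean_text(d.full_text()) for d in docs), self.config.subword_vocab_size
        )
        vocab.save(path)
        return vocab

    # ------------------------------------------------------- text encoding
    def _doc_text(self, doc: LabeledDocument, trim: bool) -> str:
        if trim and doc.text is None and doc.comprehensive:
            trimmed = trim_comprehensive(doc.comprehensive, self.config.trim_keyword)
            doc = dataclasses.replace(doc, comprehensive=trimmed)
        return clean_text(doc.full_text())

    def _encode_word_docs(
        self, docs: list[LabeledDocument], word_to_id: dict[str, int], max_len: int
    ) -> tuple[list[list[int]], list[int]]:
        ids = [
            encode_words(self._doc_text(d, trim=False), word_to_id, max_len).ids
            for d in docs
        ]
        labels = [LABEL_TO_INDEX[d.label] for d in docs]
        return ids, labels

    def _encode_subword_docs(
        self, docs: list[LabeledDocument], vocab: Vocabulary, max_len: int
    ) -> tuple[list[list[int]], list[int]]:
        ids = [
            encode(self._doc_text(d, trim=True), vocab, max_len=max_len).ids
            for d in docs
        ]
        labels = [LABEL_TO_INDEX[d.label] for d in docs]
        return ids, labels

    # ------------------------------------------------------ member training
    def train_members(self) -> None:
        cfg = self.config
        expected = [
            f"members/{arch}_{m}_test_probs.csv"
            for arch in ARCHITECTURES
            for m in range(cfg.members)
        ]
        if self._done(*expected):
            return
        (self.run_dir / "members").mkdir(exist_ok=True)
        parts = self.split()
        emb = self.train_embeddings()
        vocab = self.subword_vocab()
        words, word_to_id = emb.words, emb.word_to_id
        train_docs = parts["train_balanced"]
        word_train = self._encode_word_docs(train_docs, word_to_id, cfg.cnn.max_len)
        word_valid = self._encode_word_docs(parts["valid"], word_to_id, cfg.cnn.max_len)
        word_test = self._encode_word_docs(parts["test"], word_to_id, cfg.cnn.max_len)
        sub_train = self._encode_subword_docs(train_docs, vocab, cfg.transformer.max_len)
        sub_valid = self._encode_subword_docs(parts["valid"], vocab, cfg.transformer.max_len)
        sub_test = self._encode_subword_docs(parts["test"], vocab, cfg.transformer.max_len)
        test_ids = [d.doc_id for d in parts["test"]]

        jobs = {
            "cnn": (cfg.cnn, cfg.train_cnn, word_train, word_valid, word_test),
            "lstm": (cfg.lstm, cfg.train_lstm, word_train, word_valid, word_test),
            "transformer": (
                cfg.transformer,
                cfg.train_transformer,
                sub_train,
                sub_valid,
                sub_test,
            ),
        }
        for arch, (mcfg, tcfg, train, valid, test) in jobs.items():
            for m in range(cfg.members):
                probs_path = self._path(f"members/{arch}_{m}_test_probs.csv")
                if self.resume and probs_path.exists():
                    continue
                seed = cfg.master_seed + m
                t0 = time.time()
                if arch == "cnn":
                    model = clf.build_cnn(mcfg, embeddings=emb, seed=seed)
                elif arch == "lstm":
                    model = clf.build_lstm(mcfg, embeddings=emb, seed=seed)
                else:
                    model = clf.build_transformer(mcfg, vocab_size=len(vocab), seed=seed)
                tc = dataclasses.replace(tcfg, seed=seed)
                history = clf.train_classifier(model, train, valid, tc)
                with self._path(f"members/{arch}_{m}_history.csv").open(
                    "w", newline="", encoding="utf-8"
                ) as fh:
                    writer = csv.DictWriter(
                        fh, fieldnames=["epoch", "train_loss", "val_loss", "lr"]
                    )
                    writer.writeheader()
                    writer.writerows(history.to_rows())
                probs = clf.predict_proba(model, test[0], batch_size=tc.batch_size)
                _write_probs_csv(probs_path, test_ids, probs)
                log.info(
                    "trained %s member %d (seed %d) in %.1fs; final val loss %.4f",
                    arch, m, seed, time.time() - t0,
                    history.epochs[-1]["val_loss"] if history.epochs else float("nan"),
                )

    def ensembles(self) -> dict[str, np.ndarray]:
        names = [f"ensemble_{arch}_test_probs.csv" for arch in ARCHITECTURES]
        if not self._done(*names):
            self.train_members()
            for arch in ARCHITECTURES:
                members = []
                ids = None
                for m in range(self.config.members):
                    ids, probs = _read_probs_csv(
                        self._path(f"members/{arch}_{m}_test_probs.csv")
                    )
                    members.append(probs)
                _write_probs_csv(
                    self._path(f"ensemble_{arch}_test_probs.csv"), ids, soft_vote(members)
                )
        out = {}
        for arch in ARCHITECTURES:
            ids, probs = _read_probs_csv(self._path(f"ensemble_{arch}_test_probs.csv"))
            out[arch] = probs
            out["doc_ids"] = ids
        return out

    def scent(self) -> dict[str, list[str]]:
        names = ["scent_v1_labels.csv", "scent_v2_labels.csv"]
        ens = self.ensembles()
        ids = ens["doc_ids"]
        if not self._done(*names):
            v1 = scent_v1(ens["cnn"], ens["transformer"])
            v2 = scent_v2(ens["transformer"], ens["cnn"], ens["lstm"])
            _write_labels_csv(self._path("scent_v1_labels.csv"), ids, v1)
            _write_labels_csv(self._path("scent_v2_labels.csv"), ids, v2)
        out = {}
        for version, name in zip(("v1", "v2"), names):
            with self._path(name).open("r", encoding="utf-8") as fh:
                reader = csv.reader(fh)
                next(reader)
                out[version] = [rec[1] for rec in reader]
        return out

    def evaluate(self) -> dict:
        path = self._path("evaluation.json")
        if self._done("evaluation.json"):
            with path.open("r", encoding="utf-8") as fh:
                return json.load(fh)
        parts = self.split()
        gold = [d.label for d in parts["test"]]
        ens = self.ensembles()
        labels = self.scent()
        from .labels import severe_argmax

        systems: dict[str, list[str]] = {
            arch: [LABELS[i] for i in severe_argmax(ens[arch])] for arch in ARCHITECTURES
        }
        systems["scent_v1"] = labels["v1"]
        systems["scent_v2"] = labels["v2"]
        report = {name: evaluation_report(gold, pred) for name, pred in systems.items()}
        with path.open("w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        with self._path("evaluation.txt").open("w", encoding="utf-8") as fh:
            for name, rep in report.items():
                fh.write(f"=== {name} ===\n{format_report(rep)}\n\n")
        return report

    def run_all(self) -> dict:
        report = self.evaluate()
        self._update_manifest()
        return report


def run_experiment(
    config: ExperimentConfig, run_dir: str | Path, resume: bool = True
) -> dict:
    """Execute the full experiment; returns the evaluation report."""
    return ExperimentRunner(config, run_dir, resume=resume).run_all()
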