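"""From extracted records to a labeled binary feature matrix.

A document becomes one row over a fixed symptom-word vocabulary:
entry (i, j) is 1 iff any record of document i contains an affirmed
mention of vocabulary term j (pertinent negatives encode as 0).  Labels
come from diagnosis strings mapped through an ordered regex rule table;
documents without a clear generalized/focal classification are excluded
upstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .extraction import SeizureRecord
from .lexicon import Lexicon

logger = logging.getLogger(__name__)

GENERALIZED = "generalized"
FOCAL = "focal"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SymptomVocabulary:
    """Ordered symptom-word list backing the feature matrix columns."""

    term_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.term_ids) != len(set(self.term_ids)):
            raise ValueError("vocabulary term ids must be unique")
        if len(self.term_ids) != len(self.labels):
            raise ValueError("one display label per term id")

    def __len__(self) -> int:
        return len(self.term_ids)

    @classmethod
    def from_lexicon(cls, lexicon: Lexicon, language: str = "en") -> "SymptomVocabulary":
        """Primary symptom terms of the lexicon, in lexicon order."""
        terms = lexicon.terms_of_category("symptom")
        return cls(
            term_ids=tuple(t.term_id for t in terms),
            labels=tuple(t.labels.get(language, t.term_id) for t in terms),
        )


@dataclass
class FeatureMatrix:
    doc_ids: list[str]
    X: np.ndarray  # n_docs x n_vocab, binary
    y: np.ndarray  # n_docs labels in {generalized, focal}
    vocab: SymptomVocabulary

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y)
        if self.X.shape != (len(self.doc_ids), len(self.vocab)):
            raise ValueError("X shape inconsistent with doc_ids/vocab")
        if len(self.y) != len(self.doc_ids):
            raise ValueError("one label per document")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("X must be binary")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=list(self.vocab.labels))
        df.insert(0, "doc_id", self.doc_ids)
        df["label"] = self.y
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = tuple(c for c in df.columns if c not in ("doc_id", "label"))
        return cls(
            doc_ids=df["doc_id"].astype(str).tolist(),
            X=df[list(labels)].to_numpy(dtype=np.int8),
            y=df["label"].to_numpy(dtype=object),
            vocab=SymptomVocabulary(term_ids=labels, labels=labels),
        )


DEFAULT_DIAGNOSIS_RULES: tuple[tuple[str, str], ...] = (
    (r"generali[sz]ed", GENERALIZED),
    (r"\babsence\b", GENERALIZED),
    (r"myoclonic epilepsy", GENERALIZED),
    (r"\bfocal\b", FOCAL),
    (r"\bpartial\b", FOCAL),
    (r"temporal lobe", FOCAL),
    (r"frontal lobe", FOCAL),
)


def map_diagnosis(
    diagnosis: str,
    rules: Sequence[tuple[str, str]] = DEFAULT_DIAGNOSIS_RULES,
) -> str:
    """First matching rule wins; no match -> ``unclassified``."""
    if not rules:
        raise ValueError("empty diagnosis rule table")
    text = diagnosis.lower()
    for pattern, label in rules:
        if re.search(pattern, text):
            return label
    return UNCLASSIFIED


def build_feature_matrix(
    records: Sequence[SeizureRecord],
    vocab: SymptomVocabulary,
    labels: Mapping[str, str],
) -> FeatureMatrix:
    """Binary presence matrix over ``vocab`` from affirmed symptom mentions.

    ``labels`` maps doc_id to generalized/focal; every labeled document
    gets a row even if no record mentions a vocabulary term.  Mentions
    whose term is outside the vocabulary are ignored (counted in a log
    line); negated and uncertain mentions contribute 0.
    """
    for doc_id, label in labels.items():
        if label not in (GENERALIZED, FOCAL):
            raise ValueError(f"doc {doc_id!r} has unusable label {label!r}")
    col = {tid: j for j, tid in enumerate(vocab.term_ids)}
    doc_ids = list(labels.keys())
    row = {d: i for i, d in enumerate(doc_ids)}
    X = np.zeros((len(doc_ids), len(vocab)), dtype=np.int8)
    skipped = 0
    for rec in records:
        i = row.get(rec.doc_id)
        if i is None:
            continue
        for m in rec.symptoms:
            if m.status != "with":
                continue
            j = col.get(m.term_id)
            if j is None:
                skipped += 1
                continue
            X[i, j] = 1
    if skipped:
        logger.info("ignored %d affirmed mentions outside the vocabulary", skipped)
    y = np.array([labels[d] for d in doc_ids], dtype=object)
    return FeatureMatrix(doc_ids=doc_ids, X=X, y=y, vocab=vocab)


def split_train_test(
    fm: FeatureMatrix,
    ratio: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified train/test split at ``ratio``.

    Per class the train share is floored, then classes with the largest
    fractional remainder are topped up one by one until the train set
    holds round(ratio * n) documents; the split is seed-reproducible.
    """
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(fm.y, return_counts=True)
    if (counts < 2).any():
        raise ValueError("each class needs at least 2 documents to split")
    n = len(fm.doc_ids)
    target_train = int(round(ratio * n))
    if not stratified:
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:target_train], perm[target_train:]
    else:
        takes = {}
        remainders = []
        for c, nc in zip(classes, counts):
            exact = ratio * nc
            takes[c] = int(np.floor(exact))
            remainders.append((exact - np.floor(exact), c))
        short = target_train - sum(takes.values())
        for _, c in sorted(remainders, reverse=True)[: max(short, 0)]:
            takes[c] += 1
        train_parts, test_parts = [], []
        for c in classes:
            idx = np.flatnonzero(fm.y == c)
            idx = rng.permutation(idx)
            train_parts.append(idx[: takes[c]])
            test_parts.append(idx[takes[c] :])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.sort(np.concatenate(test_parts))

    def subset(idx: np.ndarray) -> FeatureMatrix:
        return FeatureMatrix(
            doc_ids=[fm.doc_ids[i] for i in idx],
            X=fm.X[idx],
            y=fm.y[idx],
            vocab=fm.vocab,
        )

    return subset(train_idx), subset(test_idx)
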