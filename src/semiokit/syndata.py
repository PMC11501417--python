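"""Synthetic seizure narratives with exact gold annotations.

The generator emulates the structure of a history of present illness:
each document is a sequence of temporally anchored episode descriptions
("3 years ago, the patient experienced ...") containing affirmed
symptom surfaces drawn from the lexicon, pertinent negatives about
symptoms the patient does *not* have, seizure sites, episode durations
and seizure frequencies.  Because narratives are rendered from lexicon
surfaces and unambiguous cue templates, the generator knows the exact
gold records and the planted document x symptom matrix, making the full
extraction pipeline testable without any clinical data.

Class structure is planted through class-conditional Bernoulli symptom
probabilities (generalized vs focal), so classifier recovery of the
planted separation can be measured.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import FOCAL, GENERALIZED, FeatureMatrix, SymptomVocabulary
from .extraction import (
    Duration,
    Frequency,
    Mention,
    RuleConfig,
    SeizureRecord,
    default_rules,
)
from .lexicon import Lexicon, build_surface_index
from .resources import default_lexicon

# Anchor phrases ordered from remote to recent, so sampled subsequences
# read chronologically; the first anchor always opens the document.
_ANCHORS = (
    "5 years ago",
    "3 years ago",
    "2 years ago",
    "1 year ago",
    "6 months ago",
    "3 months ago",
    "2 months ago",
    "1 month ago",
    "2 weeks ago",
    "5 days ago",
)

_DURATIONS: tuple[tuple[str, float], ...] = (
    ("10 seconds", 10.0),
    ("30 seconds", 30.0),
    ("about 1 minute", 60.0),
    ("1 to 2 minutes", 90.0),
    ("2 minutes", 120.0),
    ("5 minutes", 300.0),
)

_FREQUENCIES: tuple[tuple[str, float], ...] = (
    ("once a month", 1.0 / 30.0),
    ("twice a month", 2.0 / 30.0),
    ("once a week", 1.0 / 7.0),
    ("twice a year", 2.0 / 365.0),
    ("once a day", 1.0),
    ("3 times per day", 3.0),
    ("4 times per week", 4.0 / 7.0),
)

# Symptoms that separate generalized from focal onset in the planted
# class-conditional model (term ids of the bundled lexicon).
_GENERALIZED_MARKERS = (
    "S001",  # clonic
    "S002",  # tonic
    "S003",  # tonic-clonic
    "S008",  # unresponsive to call
    "S009",  # eyes rolled up
    "S010",  # foaming at mouth
    "S011",  # fall
    "S012",  # loss of consciousness
)
_FOCAL_MARKERS = (
    "S023",  # aura
    "S024",  # epigastric rising
    "S025",  # deja vu
    "S044",  # unilateral jerking
    "S046",  # eye deviation
    "S090",  # automatism
    "S017",  # lip smacking
    "S053",  # speech arrest
)


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    ``p_symptom_given_class`` is an (n_vocab, 2) matrix of Bernoulli
    parameters, column 0 for generalized and column 1 for focal; the
    default plants a strongly separable structure (marker symptoms at
    0.85 vs 0.15) with sparse class-independent background symptoms.
    """

    n_docs: int
    seed: int
    class_prior: float = 0.45
    p_symptom_given_class: np.ndarray | None = None
    negation_rate: float = 0.3
    anchors_per_doc: tuple[int, int] = (1, 3)
    p_location: float = 0.5
    p_duration: float = 0.6
    p_frequency: float = 0.5
    unclassified_rate: float = 0.0
    language: str = "en"
    render: bool = True

    def __post_init__(self) -> None:
        if self.n_docs < 2:
            raise ValueError("n_docs must be >= 2")
        for p in (
            self.class_prior,
            self.negation_rate,
            self.p_location,
            self.p_duration,
            self.p_frequency,
            self.unclassified_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.anchors_per_doc
        if lo < 1 or hi < lo:
            raise ValueError("anchors_per_doc must be a valid range")


def default_symptom_probabilities(vocab: SymptomVocabulary) -> np.ndarray:
    """Planted class-conditional Bernoulli parameters (vocab x 2)."""
    p = np.full((len(vocab), 2), 0.03)
    idx = {tid: j for j, tid in enumerate(vocab.term_ids)}
    for tid in _GENERALIZED_MARKERS:
        p[idx[tid]] = (0.85, 0.15)
    for tid in _FOCAL_MARKERS:
        p[idx[tid]] = (0.15, 0.85)
    return p


@dataclass
class GoldBundle:
    documents: list[dict]
    records: list[SeizureRecord]
    labels: dict[str, str]  # doc_id -> generalized/focal (all docs)
    diagnoses: dict[str, str]  # doc_id -> diagnosis string
    feature_matrix: FeatureMatrix  # planted presence matrix (classified docs)
    vocab: SymptomVocabulary

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with (outdir / "docs.jsonl").open("w", encoding="utf-8") as fh:
            for doc in self.documents:
                fh.write(json.dumps(doc, ensure_ascii=False) + "\n")
        with (outdir / "gold.jsonl").open("w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec.to_obj(), ensure_ascii=False) + "\n")
        with (outdir / "labels.csv").open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["doc_id", "label", "diagnosis"])
            for doc_id, label in self.labels.items():
                writer.writerow([doc_id, label, self.diagnoses[doc_id]])
        self.feature_matrix.to_csv(outdir / "planted_matrix.csv")


_DIAGNOSIS_TEXT = {
    GENERALIZED: "generalized tonic-clonic epilepsy",
    FOCAL: "focal epilepsy with impaired awareness",
}


def _sample_surface(rng: np.random.Generator, lexicon: Lexicon, term_id: str,
                    language: str) -> str:
    surfaces = lexicon.terms[term_id].surfaces(language)
    return surfaces[rng.integers(len(surfaces))]


class _DocBuilder:
    """Accumulates text while tracking exact character spans."""

    def __init__(self, doc_id: str) -> None:
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.pos = 0

    def add(self, s: str) -> tuple[int, int]:
        start = self.pos
        self.parts.append(s)
        self.pos += len(s)
        return (start, self.pos)

    def text(self) -> str:
        return "".join(self.parts)


def render_narrative(
    plan: dict,
    builder: _DocBuilder,
    first: bool,
) -> SeizureRecord:
    """Render one anchored episode into ``builder`` and return its gold record.

    ``plan`` holds the anchor string, affirmed symptom surfaces
    (term_id, surface), an optional negated distractor, optional
    location, duration phrase and frequency phrase.  The template keeps
    each cue and its target inside one clause so the default rule
    configuration recovers the plan exactly.
    """
    rec = SeizureRecord(doc_id=builder.doc_id, time_stamp=plan["anchor"])
    if not first:
        builder.add(" ")
    builder.add(plan["anchor"])
    symptoms: list[tuple[str, str]] = plan["symptoms"]
    if symptoms:
        builder.add(", the patient experienced ")
        for i, (term_id, surface) in enumerate(symptoms):
            if i > 0:
                builder.add(" and also ")
            span = builder.add(surface)
            rec.symptoms.append(
                Mention(surface=surface, char_span=span, term_id=term_id,
                        category="symptom", status="with")
            )
    else:
        builder.add(", the episodes recurred")
    if plan.get("location"):
        term_id, surface = plan["location"]
        builder.add(" involving the ")
        span = builder.add(surface)
        rec.locations.append(
            Mention(surface=surface, char_span=span, term_id=term_id,
                    category="location", status="with")
        )
    if plan.get("duration"):
        raw, seconds = plan["duration"]
        builder.add(", lasting ")
        builder.add(raw)
        rec.episode_time = Duration(raw=raw, seconds=seconds)
    if plan.get("frequency"):
        raw, per_day = plan["frequency"]
        builder.add(", occurring ")
        builder.add(raw)
        rec.frequency = Frequency(raw=raw, per_day=per_day)
    if plan.get("negated"):
        term_id, surface = plan["negated"]
        builder.add(", without ")
        span = builder.add(surface)
        rec.symptoms.append(
            Mention(surface=surface, char_span=span, term_id=term_id,
                    category="symptom", status="without")
        )
    builder.add(".")
    return rec


def generate_cohort(
    spec: CohortSpec,
    lexicon: Lexicon | None = None,
    vocab: SymptomVocabulary | None = None,
) -> GoldBundle:
    """Sample a labeled synthetic cohort with gold annotations.

    All randomness flows from ``spec.seed`` through per-document
    sub-streams, so equal specs yield byte-identical bundles.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    if vocab is None:
        vocab = SymptomVocabulary.from_lexicon(lexicon, spec.language)
    p = spec.p_symptom_given_class
    if p is None:
        p = default_symptom_probabilities(vocab)
    p = np.asarray(p, dtype=float)
    if p.shape != (len(vocab), 2):
        raise ValueError("p_symptom_given_class must be (n_vocab, 2)")
    missing = [t for t in vocab.term_ids if t not in lexicon.terms]
    if missing:
        raise ValueError(f"vocabulary terms absent from lexicon: {missing[:5]}")

    root = np.random.default_rng(spec.seed)
    doc_seeds = root.integers(0, 2**31 - 1, size=spec.n_docs)

    documents: list[dict] = []
    records: list[SeizureRecord] = []
    labels: dict[str, str] = {}
    diagnoses: dict[str, str] = {}
    X = np.zeros((spec.n_docs, len(vocab)), dtype=np.int8)
    classified: list[int] = []

    lo, hi = spec.anchors_per_doc
    for d in range(spec.n_docs):
        rng = np.random.default_rng(doc_seeds[d])
        doc_id = f"doc{d:05d}"
        cls = GENERALIZED if rng.random() < spec.class_prior else FOCAL
        col = 0 if cls == GENERALIZED else 1
        present = np.flatnonzero(rng.random(len(vocab)) < p[:, col])
        X[d, present] = 1
        labels[doc_id] = cls
        if rng.random() < spec.unclassified_rate:
            diagnoses[doc_id] = "epilepsy, unspecified"
        else:
            diagnoses[doc_id] = _DIAGNOSIS_TEXT[cls]
            classified.append(d)

        n_anchors = int(rng.integers(lo, hi + 1))
        n_anchors = min(n_anchors, len(_ANCHORS))
        anchor_idx = np.sort(rng.choice(len(_ANCHORS), size=n_anchors, replace=False))
        # deal each present symptom to one anchor
        assignment: list[list[int]] = [[] for _ in range(n_anchors)]
        for j in present:
            assignment[int(rng.integers(n_anchors))].append(int(j))
        absent = np.flatnonzero(X[d] == 0)

        if spec.render:
            builder = _DocBuilder(doc_id)
            for a in range(n_anchors):
                plan: dict = {
                    "anchor": _ANCHORS[anchor_idx[a]],
                    "symptoms": [
                        (
                            vocab.term_ids[j],
                            _sample_surface(rng, lexicon, vocab.term_ids[j],
                                            spec.language),
                        )
                        for j in assignment[a]
                    ],
                }
                loc_terms = lexicon.terms_of_category("location")
                if loc_terms and rng.random() < spec.p_location:
                    lt = loc_terms[int(rng.integers(len(loc_terms)))]
                    plan["location"] = (
                        lt.term_id,
                        _sample_surface(rng, lexicon, lt.term_id, spec.language),
                    )
                if rng.random() < spec.p_duration:
                    plan["duration"] = _DURATIONS[int(rng.integers(len(_DURATIONS)))]
                if rng.random() < spec.p_frequency:
                    plan["frequency"] = _FREQUENCIES[
                        int(rng.integers(len(_FREQUENCIES)))
                    ]
                if len(absent) and rng.random() < spec.negation_rate:
                    j = int(absent[rng.integers(len(absent))])
                    plan["negated"] = (
                        vocab.term_ids[j],
                        _sample_surface(rng, lexicon, vocab.term_ids[j],
                                        spec.language),
                    )
                records.append(render_narrative(plan, builder, first=(a == 0)))
            documents.append(
                {
                    "doc_id": doc_id,
                    "text": builder.text(),
                    "diagnosis": diagnoses[doc_id],
                    "lang": spec.language,
                }
            )
        else:
            documents.append(
                {"doc_id": doc_id, "text": "", "diagnosis": diagnoses[doc_id],
                 "lang": spec.language}
            )

    doc_ids = [documents[d]["doc_id"] for d in classified]
    fm = FeatureMatrix(
        doc_ids=doc_ids,
        X=X[classified],
        y=np.array([labels[d] for d in doc_ids], dtype=object),
        vocab=vocab,
    )
    return GoldBundle(
        documents=documents,
        records=records,
        labels=labels,
        diagnoses=diagnoses,
        feature_matrix=fm,
        vocab=vocab,
    )


# ---------------------------------------------------------------------------
# simulated annotators for agreement studies

STATUS_CATEGORIES = ("with", "without", "unknown")


def inject_agreement_sample(
    records: Sequence[SeizureRecord],
    n: int,
    n_annotators: int = 4,
    noise_rate: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Simulate annotators re-rating the status of sampled symptom mentions.

    ``n`` records are drawn without replacement; every symptom mention
    in them becomes one item.  Each annotator reports the gold status
    with probability 1 - noise_rate, otherwise a uniformly random other
    category.  Returns an items x 3 counts matrix over
    (with, without, unknown) suitable for Fleiss's kappa.
    """
    if n > len(records):
        raise ValueError("n exceeds the number of records")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    items = [
        STATUS_CATEGORIES.index(m.status)
        for i in sorted(idx)
        for m in records[i].symptoms
    ]
    if not items:
        raise ValueError("sampled records contain no symptom mentions")
    R = np.zeros((len(items), len(STATUS_CATEGORIES)), dtype=int)
    for i, truth in enumerate(items):
        for _ in range(n_annotators):
            if rng.random() < noise_rate:
                others = [c for c in range(len(STATUS_CATEGORIES)) if c != truth]
                R[i, others[rng.integers(len(others))]] += 1
            else:
                R[i, truth] += 1
    return R
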