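"""Scoring of extraction output against gold annotations.

Per-dimension counts (gold total, reported total, correct) follow the
manual-inspection audit design: elements are compared within the same
temporally anchored record, `correct` is the size of a maximum
one-to-one matching, and precision/recall/F1 derive from the counts.
Inter-annotator agreement uses Fleiss's kappa for a fixed number of
raters.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Hashable, Literal, Sequence

import numpy as np

from .extraction import SeizureRecord
from .lexicon import normalize_surface

DIMENSIONS = (
    "time_stamp",
    "location",
    "symptom",
    "episode_time",
    "status",
    "frequency",
)

Mode = Literal["term", "exact_text"]


@dataclass
class EvalCounts:
    dimension: str
    gold_total: int
    reported_total: int
    correct: int

    def __post_init__(self) -> None:
        if min(self.gold_total, self.reported_total, self.correct) < 0:
            raise ValueError("counts must be non-negative")
        if self.correct > min(self.gold_total, self.reported_total):
            raise ValueError("correct exceeds a total")


@dataclass
class DimensionMetrics:
    recall: float
    precision: float
    f1: float


def _record_elements(
    rec: SeizureRecord, dimension: str, mode: Mode
) -> list[Hashable]:
    """Element keys of one record for a dimension.

    ``term`` mode compares at concept level (term ids; normalized values
    for durations/frequencies); ``exact_text`` compares normalized raw
    surfaces.  The status dimension scores each symptom mention jointly
    with its status value.
    """
    if dimension == "symptom":
        return [
            m.term_id if mode == "term" else normalize_surface(m.surface)
            for m in rec.symptoms
        ]
    if dimension == "location":
        return [
            m.term_id if mode == "term" else normalize_surface(m.surface)
            for m in rec.locations
        ]
    if dimension == "status":
        return [
            (
                m.term_id if mode == "term" else normalize_surface(m.surface),
                m.status,
            )
            for m in rec.symptoms
        ]
    if dimension == "episode_time":
        if rec.episode_time is None:
            return []
        if mode == "term":
            return [round(rec.episode_time.seconds, 6)]
        return [normalize_surface(rec.episode_time.raw)]
    if dimension == "frequency":
        if rec.frequency is None:
            return []
        if mode == "term":
            return [round(rec.frequency.per_day, 9)]
        return [normalize_surface(rec.frequency.raw)]
    raise ValueError(f"unknown dimension {dimension!r}")


def _pair_records(
    gold: Sequence[SeizureRecord], pred: Sequence[SeizureRecord]
) -> list[tuple[SeizureRecord, SeizureRecord]]:
    """Pair gold/pred records of one document by anchor string, in order."""
    by_ts: dict[str, list[SeizureRecord]] = {}
    for r in pred:
        by_ts.setdefault(normalize_surface(r.time_stamp), []).append(r)
    pairs = []
    for g in gold:
        bucket = by_ts.get(normalize_surface(g.time_stamp))
        if bucket:
            pairs.append((g, bucket.pop(0)))
    return pairs


def align_elements(
    gold: Sequence[SeizureRecord],
    pred: Sequence[SeizureRecord],
    dimension: str,
    mode: Mode = "term",
) -> EvalCounts:
    """Count gold/reported/correct elements for one framework dimension.

    ``correct`` is the size of a maximum one-to-one matching between the
    two element multisets, record by record (for identical keys this is
    the multiset intersection).  Time stamps are matched at document
    level since they define the records themselves.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    gold_by_doc: dict[str, list[SeizureRecord]] = {}
    pred_by_doc: dict[str, list[SeizureRecord]] = {}
    for r in gold:
        gold_by_doc.setdefault(r.doc_id, []).append(r)
    for r in pred:
        pred_by_doc.setdefault(r.doc_id, []).append(r)

    gold_total = reported_total = correct = 0
    for doc_id in gold_by_doc.keys() | pred_by_doc.keys():
        g_recs = gold_by_doc.get(doc_id, [])
        p_recs = pred_by_doc.get(doc_id, [])
        if dimension == "time_stamp":
            g_elems = Counter(normalize_surface(r.time_stamp) for r in g_recs)
            p_elems = Counter(normalize_surface(r.time_stamp) for r in p_recs)
            gold_total += sum(g_elems.values())
            reported_total += sum(p_elems.values())
            correct += sum((g_elems & p_elems).values())
            continue
        for r in g_recs:
            gold_total += len(_record_elements(r, dimension, mode))
        for r in p_recs:
            reported_total += len(_record_elements(r, dimension, mode))
        for g_rec, p_rec in _pair_records(g_recs, p_recs):
            g_elems = Counter(_record_elements(g_rec, dimension, mode))
            p_elems = Counter(_record_elements(p_rec, dimension, mode))
            correct += sum((g_elems & p_elems).values())
    return EvalCounts(dimension, gold_total, reported_total, correct)


def prf(counts: EvalCounts) -> DimensionMetrics:
    """Precision, recall and F1 from raw counts; 0/0 cases return 0."""
    if counts.gold_total == 0 and counts.reported_total == 0:
        warnings.warn(
            f"dimension {counts.dimension!r}: no gold or reported elements; "
            "metrics degenerate to 0",
            stacklevel=2,
        )
        return DimensionMetrics(0.0, 0.0, 0.0)
    recall = counts.correct / counts.gold_total if counts.gold_total else 0.0
    precision = (
        counts.correct / counts.reported_total if counts.reported_total else 0.0
    )
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return DimensionMetrics(recall=recall, precision=precision, f1=f1)


def _round_half_up(x: float, digits: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(1).scaleb(-digits), ROUND_HALF_UP))


def table_row(counts: EvalCounts) -> dict[str, float]:
    """Audit-table presentation of the counts.

    Recall and precision are percentages rounded half-up to integers;
    F1 is the harmonic mean of the 2-dp-rounded precision and recall,
    rounded half-up to 2 dp — the arithmetic that reproduces published
    audit tables where F1 is derived from the displayed fractions.
    """
    m = prf(counts)
    p2 = _round_half_up(m.precision, 2)
    r2 = _round_half_up(m.recall, 2)
    f1 = 2 * p2 * r2 / (p2 + r2) if p2 + r2 > 0 else 0.0
    return {
        "recall_pct": _round_half_up(100 * m.recall, 0),
        "precision_pct": _round_half_up(100 * m.precision, 0),
        "f1": _round_half_up(f1, 2),
    }


def evaluate_all(
    gold: Sequence[SeizureRecord],
    pred: Sequence[SeizureRecord],
    mode: Mode = "term",
) -> dict[str, dict]:
    """Counts and metrics for every framework dimension."""
    out: dict[str, dict] = {}
    for dim in DIMENSIONS:
        counts = align_elements(gold, pred, dim, mode=mode)
        metrics = (
            prf(counts)
            if counts.gold_total or counts.reported_total
            else DimensionMetrics(0.0, 0.0, 0.0)
        )
        out[dim] = {
            "gold_total": counts.gold_total,
            "reported_total": counts.reported_total,
            "correct": counts.correct,
            "recall": metrics.recall,
            "precision": metrics.precision,
            "f1": metrics.f1,
        }
    return out


# ---------------------------------------------------------------------------
# inter-annotator agreement


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss's kappa for ``ratings`` (items x categories counts).

    Every item must be rated by the same number of raters m >= 2.
    Returns (P̄ − P̄e) / (1 − P̄e); perfect agreement gives 1.0.  When
    expected agreement P̄e is 1 (a single category used everywhere) the
    statistic is undefined and a ValueError is raised.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[0] < 1 or R.shape[1] < 2:
        raise ValueError("ratings must be items x categories with >= 2 categories")
    if np.any(R < 0):
        raise ValueError("ratings counts must be non-negative")
    row_sums = R.sum(axis=1)
    m = row_sums[0]
    if m < 2 or not np.all(row_sums == m):
        raise ValueError("every item needs the same number of raters (>= 2)")
    n = R.shape[0]
    p_j = R.sum(axis=0) / (n * m)
    p_bar_e = float(np.sum(p_j**2))
    if p_bar_e >= 1.0:
        raise ValueError("single category used everywhere; kappa undefined")
    p_i = (np.sum(R**2, axis=1) - m) / (m * (m - 1))
    p_bar = float(np.mean(p_i))
    return (p_bar - p_bar_e) / (1.0 - p_bar_e)


def sample_for_review(
    records: Sequence, n: int, seed: int
) -> list:
    """Uniform sample without replacement for manual inspection."""
    if n > len(records):
        raise ValueError(f"cannot sample {n} from {len(records)} records")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    return [records[i] for i in sorted(idx)]
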