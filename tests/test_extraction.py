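import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semiokit.extraction import (
    Duration,
    Frequency,
    Mention,
    assign_status,
    default_rules,
    detect_timestamps,
    extract_document,
    match_terms,
    parse_duration,
    parse_frequency,
    segment_clauses,
)
from semiokit.lexicon import Lexicon, Term, build_surface_index, normalize_text


# ---------------------------------------------------------------------------
# clause segmentation


def test_segment_basic(rules):
    assert len(segment_clauses("A; B.", rules)) == 2
    text = "no punctuation at all"
    clauses = segment_clauses(text, rules)
    assert len(clauses) == 1 and clauses[0][1] == (0, len(text))
    assert segment_clauses("   \n ", rules) == []


def test_segment_splits_at_connectives(rules):
    clauses = [c for c, _ in segment_clauses("no tonic but clonic jerking", rules)]
    assert clauses == ["no tonic ", "but clonic jerking"]


@settings(max_examples=100, deadline=None)
@given(st.text(alphabet="ab .;,!但了x ", min_size=1, max_size=60))
def test_segment_partition_property(text):
    rules = default_rules()
    clauses = segment_clauses(text, rules)
    if not text.strip():
        assert clauses == []
        return
    # spans are contiguous, non-overlapping, and cover the text
    assert clauses[0][1][0] == 0
    assert clauses[-1][1][1] == len(text)
    for (ca, (a1, b1)), (cb, (a2, b2)) in zip(clauses, clauses[1:]):
        assert b1 == a2
    assert "".join(c for c, _ in clauses) == text
    for c, (a, b) in clauses:
        assert text[a:b] == c


# ---------------------------------------------------------------------------
# term matching


def test_phrase_extracted_whole(toy_lexicon):
    idx = build_surface_index(toy_lexicon, "en")
    mentions = match_terms("tonic clonic seizure", idx)
    assert [m.surface for m in mentions] == ["tonic clonic seizure"]
    assert mentions[0].term_id == "T1"


def test_no_match_returns_empty(toy_lexicon):
    idx = build_surface_index(toy_lexicon, "en")
    assert match_terms("nothing relevant here", idx) == []


def test_mention_spans_slice_raw_text(index):
    text = "He had FOAMING AT MOUTH then fell."
    for m in match_terms(text, index):
        assert text[m.char_span[0] : m.char_span[1]] == m.surface


def test_latin_boundary_blocks_substring_matches(index):
    # "tonic" must not fire inside "catatonic"; "fall" not inside "fallacy"
    assert all(m.surface != "tonic" for m in match_terms("catatonic state", index))
    assert match_terms("a fallacy", index) == []


def _brute_force_leftmost_longest(clause, idx):
    """Oracle: enumerate every boundary-valid match, then schedule
    leftmost-longest non-overlapping intervals."""
    norm = normalize_text(clause)
    matches = []
    for i in range(len(norm)):
        for j in range(i + 1, len(norm) + 1):
            cand = norm[i:j]
            if cand != cand.strip() or cand.strip() not in idx.entries:
                continue
            before = norm[i - 1] if i > 0 else " "
            after = norm[j] if j < len(norm) else " "
            if cand[0].isascii() and before.isalnum() and before.isascii():
                continue
            if cand[-1].isascii() and after.isalnum() and after.isascii():
                continue
            matches.append((i, j))
    chosen, pos = [], 0
    while True:
        avail = [(i, j) for i, j in matches if i >= pos]
        if not avail:
            break
        start = min(i for i, _ in avail)
        j = max(j for i, j in avail if i == start)
        chosen.append((start, j))
        pos = j
    return chosen


def test_matching_equals_brute_force_oracle():
    rng = np.random.default_rng(0)
    words = ["to", "tonic", "tonic cl", "tonic clonic", "clo", "clonic", "jerk",
             "jerking", "arm", "left arm", "a b", "ab", "ba", "b", "xx yy",
             "xx", "yy", "zz", "q", "tonic clonic jerk"]
    terms = {
        f"T{i}": Term(f"T{i}", {"en": w}, {}, "symptom") for i, w in enumerate(words)
    }
    idx = build_surface_index(
        Lexicon(name="o", version="1", languages=["en"], terms=terms), "en"
    )
    alphabet = list("tonicclje arbxyzq ")
    for _ in range(300):
        n = int(rng.integers(1, 41))
        clause = "".join(rng.choice(alphabet, size=n))
        got = [(m.char_span[0], m.char_span[1]) for m in match_terms(clause, idx)]
        assert got == _brute_force_leftmost_longest(clause, idx), clause


def test_every_mention_term_exists_in_lexicon(lexicon, index):
    text = "3 years ago he had clonic jerking and tonic stiffening of the left arm."
    for m in match_terms(text, index):
        assert m.term_id in lexicon.terms


# ---------------------------------------------------------------------------
# status assignment


def _first_symptom(clause, index):
    return [m for m in match_terms(clause, index) if m.category == "symptom"][0]


def test_negated_mention(index, rules):
    clause = "without loss of consciousness"
    m = _first_symptom(clause, index)
    assert assign_status(m, clause, rules) == "without"


def test_default_affirmed(index, rules):
    clause = "loss of consciousness"
    m = _first_symptom(clause, index)
    assert assign_status(m, clause, rules) == "with"


def test_connective_breaks_negation_scope(index, rules):
    # run on the unsegmented clause so the in-clause scope break is exercised
    clause = "no tonic but clonic jerking"
    mentions = [m for m in match_terms(clause, index) if m.category == "symptom"]
    statuses = {m.surface: assign_status(m, clause, rules) for m in mentions}
    assert statuses == {"tonic": "without", "clonic jerking": "with"}


def test_uncertainty_cue_yields_unknown(index, rules):
    clause = "possibly tonic stiffening"
    m = _first_symptom(clause, index)
    assert assign_status(m, clause, rules) == "unknown"


def test_negation_beyond_window_does_not_fire(index, rules):
    clause = "no history of any of the previously documented recurrent tonic"
    m = _first_symptom(clause, index)
    assert assign_status(m, clause, rules) == "with"


# ---------------------------------------------------------------------------
# temporal normalization


@pytest.mark.parametrize(
    "clause,seconds",
    [
        ("lasting 2 minutes", 120.0),
        ("lasting 1-2 minutes", 90.0),
        ("1 to 2 minutes", 90.0),
        ("about 30 seconds", 30.0),
        ("for one hour", 3600.0),
    ],
)
def test_parse_duration(clause, seconds, rules):
    d = parse_duration(clause, rules)
    assert d is not None and d.seconds == seconds
    assert d.raw in clause


@pytest.mark.parametrize("clause", ["for a while", "no duration here", "2 minutes ago"])
def test_parse_duration_rejects_nonnumeric_and_timestamps(clause, rules):
    assert parse_duration(clause, rules) is None


@pytest.mark.parametrize(
    "clause,per_day",
    [
        ("once a month", 1.0 / 30.0),
        ("3 times per day", 3.0),
        ("twice a year", 2.0 / 365.0),
        ("every 2 weeks", 1.0 / 14.0),
        ("4 times per week", 4.0 / 7.0),
    ],
)
def test_parse_frequency(clause, per_day, rules):
    f = parse_frequency(clause, rules)
    assert f is not None
    assert f.per_day == pytest.approx(per_day)


def test_parse_frequency_absent(rules):
    assert parse_frequency("no frequency stated", rules) is None


def test_duration_and_frequency_require_positive_values():
    with pytest.raises(ValueError):
        Duration(raw="0 s", seconds=0)
    with pytest.raises(ValueError):
        Frequency(raw="never", per_day=0)


# ---------------------------------------------------------------------------
# temporal anchors


def test_two_anchors_in_order(rules):
    text = "3 years ago he fell. 2 months ago it worsened."
    anchors = detect_timestamps(text, rules)
    assert [a for a, _ in anchors] == ["3 years ago", "2 months ago"]


def test_implicit_onset_anchor(rules):
    assert detect_timestamps("no temporal cue at all", rules) == [("onset", 0)]


def test_anchor_offsets_strictly_increasing(rules):
    rng = np.random.default_rng(1)
    pieces = ["3 years ago", "later", "x y z", "2 weeks ago", "subsequently", "w"]
    for _ in range(50):
        text = " ".join(rng.choice(pieces, size=rng.integers(1, 8)))
        offsets = [off for _, off in detect_timestamps(text, rules)]
        assert offsets == sorted(set(offsets))


# ---------------------------------------------------------------------------
# document extraction


def test_single_symptom_document(lexicon, rules):
    records = extract_document(("d1", "clonic jerking"), lexicon, rules)
    assert len(records) == 1
    rec = records[0]
    assert rec.time_stamp == "onset"
    assert [m.status for m in rec.symptoms] == ["with"]


def test_two_anchor_note_recovers_planted_structure(lexicon, rules):
    text = (
        "3 years ago, the patient experienced tonic stiffening and also "
        "clonic jerking, without foaming at mouth, lasting 30 seconds. "
        "2 months ago, the patient experienced staring, occurring once a month."
    )
    records = extract_document(("d2", text), lexicon, rules)
    assert [r.time_stamp for r in records] == ["3 years ago", "2 months ago"]
    first, second = records
    assert {(m.term_id, m.status) for m in first.symptoms} == {
        ("S002", "with"), ("S001", "with"), ("S010", "without")
    }
    assert first.episode_time.seconds == 30.0
    assert second.frequency.per_day == pytest.approx(1.0 / 30.0)
    assert second.episode_time is None


def test_framework_note_populates_all_six_slots(lexicon, rules):
    text = (
        "2 years ago, the patient experienced clonic jerking involving the "
        "left arm, without loss of consciousness, lasting 2 minutes, "
        "occurring once a month."
    )
    (rec,) = extract_document(("d3", text), lexicon, rules)
    assert rec.time_stamp == "2 years ago"
    assert [m.term_id for m in rec.locations] == ["L001"]
    statuses = {m.term_id: m.status for m in rec.symptoms}
    assert statuses == {"S001": "with", "S012": "without"}
    assert rec.episode_time.seconds == 120.0
    assert rec.frequency.per_day == pytest.approx(1.0 / 30.0)


def test_extraction_deterministic_and_empty_text(lexicon, rules):
    text = "3 years ago tonic, later clonic."
    a = extract_document(("d", text), lexicon, rules)
    b = extract_document(("d", text), lexicon, rules)
    assert [r.to_obj() for r in a] == [r.to_obj() for r in b]
    assert extract_document(("d", "   "), lexicon, rules) == []


def test_mention_spans_within_anchor_segment(lexicon, rules):
    text = "3 years ago tonic stiffening. 1 month ago clonic jerking."
    records = extract_document(("d", text), lexicon, rules)
    anchors = detect_timestamps(text, rules)
    bounds = [off for _, off in anchors] + [len(text)]
    for rec, lo, hi in zip(records, bounds, bounds[1:]):
        for m in rec.symptoms + rec.locations:
            assert lo <= m.char_span[0] < hi
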