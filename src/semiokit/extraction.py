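"""Rule-based extraction of structured seizure records from narrative text.

The pipeline mirrors how an epileptologist reads a history of present
illness: find the temporal anchors that chapter the narrative ("3 years
ago", "subsequently"), split the text into clauses, match clause text
against the semiology lexicon with a leftmost-longest scanner, decide
for each symptom/site mention whether it is affirmed, denied or
uncertain from nearby cue words, normalize episode durations to seconds
and seizure frequencies to events per day, and file everything under the
nearest preceding anchor as one :class:`SeizureRecord` per anchor.

Cue scope is resolved by clause segmentation plus a windowed pre-mention
rule behind the :class:`ScopeResolver` interface, so a parser-backed
resolver can be plugged in without touching the engine.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from .lexicon import Lexicon, SurfaceIndex, build_surface_index, normalize_text

logger = logging.getLogger(__name__)

STATUS_VALUES = ("with", "without", "unknown")

_WORD_NUMBERS = {
    "a": 1.0,
    "an": 1.0,
    "one": 1.0,
    "two": 2.0,
    "three": 3.0,
    "four": 4.0,
    "five": 5.0,
    "six": 6.0,
    "seven": 7.0,
    "eight": 8.0,
    "nine": 9.0,
    "ten": 10.0,
}
_COUNT_WORDS = {"once": 1.0, "twice": 2.0, "thrice": 3.0}

_NUM = r"(?:\d+(?:\.\d+)?|" + "|".join(
    w for w in _WORD_NUMBERS if w not in ("a", "an")
) + r")"
_RANGE_SEP = r"\s*(?:to|-|–|—|~)\s*"


def _to_number(token: str) -> float:
    token = token.strip().lower()
    if token in _COUNT_WORDS:
        return _COUNT_WORDS[token]
    if token in _WORD_NUMBERS:
        return _WORD_NUMBERS[token]
    return float(token)


@dataclass
class Mention:
    """A lexicon hit in the document text.

    ``char_span`` is a 0-based half-open span into the *raw* document
    (character offsets, CJK-safe); slicing the document at the span
    yields ``surface`` verbatim.  ``status`` is populated only for
    symptom and location mentions.
    """

    surface: str
    char_span: tuple[int, int]
    term_id: str
    category: str
    status: str | None = None


@dataclass
class Duration:
    """Episode duration; ranges normalize to their arithmetic midpoint."""

    raw: str
    seconds: float

    def __post_init__(self) -> None:
        if self.seconds <= 0:
            raise ValueError("duration must be positive")


@dataclass
class Frequency:
    """Seizure frequency normalized to events per day (month=30 d, year=365 d)."""

    raw: str
    per_day: float

    def __post_init__(self) -> None:
        if self.per_day <= 0:
            raise ValueError("frequency must be positive")


@dataclass
class SeizureRecord:
    """One temporally anchored seizure description (the six framework slots)."""

    doc_id: str
    time_stamp: str
    symptoms: list[Mention] = field(default_factory=list)
    locations: list[Mention] = field(default_factory=list)
    episode_time: Duration | None = None
    frequency: Frequency | None = None

    def to_obj(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "time_stamp": self.time_stamp,
            "symptoms": [_mention_obj(m) for m in self.symptoms],
            "locations": [_mention_obj(m) for m in self.locations],
            "episode_time": asdict(self.episode_time) if self.episode_time else None,
            "frequency": asdict(self.frequency) if self.frequency else None,
        }

    @classmethod
    def from_obj(cls, obj: dict) -> "SeizureRecord":
        return cls(
            doc_id=obj["doc_id"],
            time_stamp=obj["time_stamp"],
            symptoms=[_mention_from_obj(m) for m in obj.get("symptoms", [])],
            locations=[_mention_from_obj(m) for m in obj.get("locations", [])],
            episode_time=Duration(**obj["episode_time"])
            if obj.get("episode_time")
            else None,
            frequency=Frequency(**obj["frequency"]) if obj.get("frequency") else None,
        )


def _mention_obj(m: Mention) -> dict:
    return {
        "surface": m.surface,
        "span": list(m.char_span),
        "term_id": m.term_id,
        "category": m.category,
        "status": m.status,
    }


def _mention_from_obj(obj: dict) -> Mention:
    return Mention(
        surface=obj["surface"],
        char_span=tuple(obj["span"]),
        term_id=obj["term_id"],
        category=obj["category"],
        status=obj.get("status"),
    )


# ---------------------------------------------------------------------------
# rule configuration


@dataclass
class RuleConfig:
    """Cue lists, pattern tables, and scope settings for the engine."""

    negation_cues: list[str]
    uncertainty_cues: list[str]
    connectives: list[str]
    temporal_adverbs: list[str]
    duration_units: dict[str, float]  # unit surface -> seconds
    frequency_periods: dict[str, float]  # period surface -> days
    scope_direction: str = "pre"
    scope_window_tokens: int = 6
    scope_window_chars: int = 10  # for unsegmented CJK context
    clause_punctuation: str = ".;!?,。；！？，\n"

    def __post_init__(self) -> None:
        if self.scope_direction not in ("pre", "post", "both"):
            raise ValueError(f"bad scope_direction {self.scope_direction!r}")
        if not self.negation_cues:
            raise ValueError("negation_cues must be non-empty")
        self._duration_re = _compile_duration(self.duration_units)
        self._frequency_res = _compile_frequency(self.frequency_periods)
        self._connective_re = _cue_regex(self.connectives) if self.connectives else None
        self._negation_re = _cue_regex(self.negation_cues)
        self._uncertainty_re = (
            _cue_regex(self.uncertainty_cues) if self.uncertainty_cues else None
        )
        self._timestamp_res = _compile_timestamps(self.temporal_adverbs)


def _cue_regex(cues: Sequence[str]) -> re.Pattern[str]:
    alts = sorted((re.escape(normalize_text(c)) for c in cues), key=len, reverse=True)
    return re.compile(r"(?<![a-z0-9])(?:" + "|".join(alts) + r")(?![a-z0-9])")


def _compile_duration(units: dict[str, float]) -> re.Pattern[str]:
    if not units:
        raise ValueError("duration_units must be non-empty")
    alts = "|".join(
        sorted((re.escape(u.lower()) for u in units), key=len, reverse=True)
    )
    # "(?!\s*ago)" keeps relative time stamps like "2 minutes ago" from
    # being read as episode durations
    return re.compile(
        rf"(?<![a-z0-9])(?:about |around |approximately )?"
        rf"({_NUM})(?:{_RANGE_SEP}({_NUM}))?\s*({alts})(?![a-z])(?!\s*ago)"
    )


def _compile_frequency(periods: dict[str, float]) -> list[re.Pattern[str]]:
    if not periods:
        raise ValueError("frequency_periods must be non-empty")
    alts = "|".join(
        sorted((re.escape(p.lower()) for p in periods), key=len, reverse=True)
    )
    count = r"(once|twice|thrice|" + _NUM + r")"
    return [
        # "once a month", "3 times per day", "twice every week"
        re.compile(
            rf"(?<![a-z0-9]){count}(?:\s+times?)?\s+(?:per|a|an|every)\s+({alts})(?![a-z])"
        ),
        # "every 2 weeks" -> 1 event per 2*period
        re.compile(rf"(?<![a-z0-9])every\s+({_NUM})\s+({alts})s?(?![a-z])"),
    ]


_RELATIVE_TIME = (
    r"(?:\d+(?:\.\d+)?|"
    + "|".join(w for w in _WORD_NUMBERS if w not in ("an",))
    + r")\s+(?:day|week|month|year)s?\s+(?:ago|earlier|prior)"
)
_OTHER_TIME = (
    r"since (?:childhood|birth|infancy|age \d+)",
    r"at (?:the )?age (?:of )?\d+",
    r"in (?:19|20)\d\d",
)


def _compile_timestamps(temporal_adverbs: Sequence[str]) -> list[re.Pattern[str]]:
    pats = [re.compile(r"(?<![a-z0-9])" + _RELATIVE_TIME + r"(?![a-z])")]
    pats += [re.compile(r"(?<![a-z0-9])" + p + r"(?![a-z0-9])") for p in _OTHER_TIME]
    if temporal_adverbs:
        pats.append(_cue_regex(temporal_adverbs))
    return pats


def default_rules() -> RuleConfig:
    """English rule set used by the bundled lexicon and the simulator."""
    return RuleConfig(
        negation_cues=[
            "no",
            "not",
            "without",
            "denies",
            "denied",
            "never",
            "free of",
        ],
        uncertainty_cues=[
            "possibly",
            "possible",
            "uncertain",
            "unclear",
            "questionable",
            "may have",
            "might have",
            "suspected",
        ],
        connectives=["but", "however", "although", "though", "whereas", "yet"],
        temporal_adverbs=[
            "initially",
            "subsequently",
            "later",
            "afterwards",
            "thereafter",
            "recently",
        ],
        duration_units={
            "second": 1.0,
            "seconds": 1.0,
            "sec": 1.0,
            "secs": 1.0,
            "s": 1.0,
            "minute": 60.0,
            "minutes": 60.0,
            "min": 60.0,
            "mins": 60.0,
            "hour": 3600.0,
            "hours": 3600.0,
            "hr": 3600.0,
            "hrs": 3600.0,
            "h": 3600.0,
        },
        frequency_periods={
            "day": 1.0,
            "days": 1.0,
            "night": 1.0,
            "week": 7.0,
            "weeks": 7.0,
            "month": 30.0,
            "months": 30.0,
            "year": 365.0,
            "years": 365.0,
        },
    )


# ---------------------------------------------------------------------------
# clause segmentation


def segment_clauses(
    text: str, cfg: RuleConfig | None = None
) -> list[tuple[str, tuple[int, int]]]:
    """Partition ``text`` into clauses at sentence punctuation and connectives.

    Spans are contiguous, non-overlapping, and cover the whole text, so
    downstream character offsets remain document offsets.  Separators
    attach to the preceding clause.  Whitespace-only text yields no
    clauses.
    """
    if cfg is None:
        cfg = default_rules()
    if not text.strip():
        return []
    norm = normalize_text(text)
    # cut *after* every punctuation run, and *before* every connective
    cuts: set[int] = set()
    punct = set(cfg.clause_punctuation)
    for i, c in enumerate(text):
        if c in punct and (i + 1 == len(text) or text[i + 1] not in punct):
            cuts.add(i + 1)
    if cfg._connective_re is not None:
        for m in cfg._connective_re.finditer(norm):
            cuts.add(m.start())
    bounds = sorted(cuts | {0, len(text)})
    out: list[tuple[str, tuple[int, int]]] = []
    for a, b in zip(bounds, bounds[1:]):
        piece = text[a:b]
        if piece.strip():
            out.append((piece, (a, b)))
        elif out:
            # glue whitespace-only fragments to the previous clause so the
            # spans still partition the text
            prev, (pa, _) = out[-1]
            out[-1] = (text[pa:b], (pa, b))
        else:
            out.append((piece, (a, b)))
    if len(out) == 1 and not out[0][0].strip():
        return []
    return out


# ---------------------------------------------------------------------------
# term matching


def match_terms(
    clause: str, index: SurfaceIndex, offset: int = 0
) -> list[Mention]:
    """Greedy leftmost-longest, non-overlapping dictionary matching.

    At each position the longest index entry starting there wins, which
    realizes the coarsest-granularity rule: a fixed phrase such as
    "tonic clonic" is extracted whole rather than as its sub-terms.
    Latin-script matches must sit on alphanumeric boundaries; CJK text
    needs no boundary.  ``offset`` shifts spans to document coordinates.
    """
    norm = normalize_text(clause)
    n = len(norm)
    out: list[Mention] = []
    i = 0
    while i < n:
        hit = None
        for length in index.lengths:
            if i + length > n:
                continue
            cand = norm[i : i + length]
            entry = index.entries.get(cand.strip())
            if entry is None:
                continue
            if cand != cand.strip():  # surface with outer whitespace: skip
                continue
            if _alnum(norm, i - 1) and cand[0].isascii():
                continue
            if _alnum(norm, i + length) and cand[-1].isascii():
                continue
            hit = (length, entry)
            break
        if hit is None:
            i += 1
            continue
        length, (term_id, category) = hit
        out.append(
            Mention(
                surface=clause[i : i + length],
                char_span=(offset + i, offset + i + length),
                term_id=term_id,
                category=category,
            )
        )
        i += length
    return out


def _alnum(s: str, i: int) -> bool:
    return 0 <= i < len(s) and (s[i].isalnum() and s[i].isascii())


# ---------------------------------------------------------------------------
# status assignment


class ScopeResolver(Protocol):
    """Decides the occurrence status of a mention from its clause context."""

    def resolve(self, mention: Mention, clause: str, clause_start: int,
                cfg: RuleConfig) -> str: ...


class WindowScopeResolver:
    """Cue-window scope: a negation/uncertainty cue within ``scope_window``
    tokens (characters for CJK) before the mention, with no intervening
    connective, flips the status.  The nearest in-scope cue wins."""

    def resolve(
        self, mention: Mention, clause: str, clause_start: int, cfg: RuleConfig
    ) -> str:
        rel = mention.char_span[0] - clause_start
        pre = normalize_text(clause[:rel])
        best: tuple[int, str] | None = None  # (cue end, status)
        for pattern, status in (
            (cfg._negation_re, "without"),
            (cfg._uncertainty_re, "unknown"),
        ):
            if pattern is None:
                continue
            for m in pattern.finditer(pre):
                gap = pre[m.end() :]
                if _has_cjk(gap):
                    in_window = len(gap.strip()) <= cfg.scope_window_chars
                else:
                    in_window = len(gap.split()) <= cfg.scope_window_tokens
                if not in_window:
                    continue
                if cfg._connective_re is not None and cfg._connective_re.search(gap):
                    continue  # connective breaks the cue's scope
                if best is None or m.end() > best[0]:
                    best = (m.end(), status)
        return best[1] if best is not None else "with"


def _has_cjk(s: str) -> bool:
    return any("一" <= c <= "鿿" for c in s)


def assign_status(
    mention: Mention,
    clause: str,
    cfg: RuleConfig,
    clause_start: int = 0,
    resolver: ScopeResolver | None = None,
) -> str:
    """Status for a symptom/location mention within its clause."""
    if resolver is None:
        resolver = WindowScopeResolver()
    return resolver.resolve(mention, clause, clause_start, cfg)


# ---------------------------------------------------------------------------
# temporal normalization


def parse_duration(clause: str, cfg: RuleConfig) -> Duration | None:
    """First duration expression in the clause, normalized to seconds."""
    norm = normalize_text(clause)
    for m in cfg._duration_re.finditer(norm):
        lo, hi, unit = m.group(1), m.group(2), m.group(3)
        try:
            value = _to_number(lo)
            if hi is not None:
                value = (value + _to_number(hi)) / 2.0
        except ValueError:
            logger.warning("unparseable duration number in %r", m.group(0))
            continue
        seconds = value * cfg.duration_units[unit]
        if seconds <= 0:
            continue
        return Duration(raw=clause[m.start() : m.end()], seconds=seconds)
    return None


def parse_frequency(clause: str, cfg: RuleConfig) -> Frequency | None:
    """First frequency expression, normalized to events per day."""
    norm = normalize_text(clause)
    matches: list[tuple[int, re.Match[str], bool]] = []
    count_pat, every_pat = cfg._frequency_res
    for m in count_pat.finditer(norm):
        matches.append((m.start(), m, True))
    for m in every_pat.finditer(norm):
        matches.append((m.start(), m, False))
    for _, m, is_count in sorted(matches, key=lambda t: t[0]):
        try:
            number = _to_number(m.group(1))
        except ValueError:
            logger.warning("unparseable frequency number in %r", m.group(0))
            continue
        days = cfg.frequency_periods[m.group(2)]
        per_day = number / days if is_count else 1.0 / (number * days)
        if per_day <= 0:
            continue
        return Frequency(raw=clause[m.start() : m.end()], per_day=per_day)
    return None


def _duration_span(clause: str, cfg: RuleConfig) -> int | None:
    m = cfg._duration_re.search(normalize_text(clause))
    return m.start() if m else None


# ---------------------------------------------------------------------------
# temporal anchors


def detect_timestamps(text: str, cfg: RuleConfig) -> list[tuple[str, int]]:
    """Temporal anchors (raw string, char offset) in document order.

    The implicit anchor ``("onset", 0)`` is prepended when nothing
    explicit starts the document, so every extraction has at least one
    record to file content under.
    """
    norm = normalize_text(text)
    found: dict[int, tuple[int, str]] = {}
    for pat in cfg._timestamp_res:
        for m in pat.finditer(norm):
            prev = found.get(m.start())
            if prev is None or m.end() > prev[0]:
                found[m.start()] = (m.end(), text[m.start() : m.end()])
    anchors: list[tuple[str, int]] = []
    last_end = -1
    for start in sorted(found):
        end, raw = found[start]
        if start < last_end:  # overlapping weaker match
            continue
        anchors.append((raw, start))
        last_end = end
    if not anchors or anchors[0][1] != 0:
        anchors.insert(0, ("onset", 0))
    return anchors


# ---------------------------------------------------------------------------
# document-level extraction


def extract_document(
    doc: tuple[str, str],
    lexicon: Lexicon | SurfaceIndex,
    cfg: RuleConfig | None = None,
    language: str = "en",
    resolver: ScopeResolver | None = None,
) -> list[SeizureRecord]:
    """Extract one :class:`SeizureRecord` per temporal anchor of ``doc``.

    Mentions, durations and frequencies attach to the nearest anchor at
    or before their character offset.  The first duration/frequency per
    record wins; extraction is deterministic for fixed inputs.
    """
    doc_id, text = doc
    if cfg is None:
        cfg = default_rules()
    if not text.strip():
        return []
    index = (
        lexicon
        if isinstance(lexicon, SurfaceIndex)
        else build_surface_index(lexicon, language)
    )
    anchors = detect_timestamps(text, cfg)
    offsets = [off for _, off in anchors]
    records = [SeizureRecord(doc_id=doc_id, time_stamp=raw) for raw, _ in anchors]

    def record_at(pos: int) -> SeizureRecord:
        k = 0
        for j, off in enumerate(offsets):
            if off <= pos:
                k = j
            else:
                break
        return records[k]

    anchor_spans = [
        (off, off + len(raw)) for raw, off in anchors if raw != "onset" or off > 0
    ]

    for clause, (start, _end) in segment_clauses(text, cfg):
        mentions = match_terms(clause, index, offset=start)
        # mask matched surfaces so a cue word *inside* one mention (e.g.
        # the "no" of "no response to calling") cannot scope over another
        masked = list(clause)
        for m in mentions:
            a, b = m.char_span[0] - start, m.char_span[1] - start
            masked[a:b] = "x" * (b - a)
        masked_clause = "".join(masked)
        for mention in mentions:
            if any(
                a <= mention.char_span[0] < b for a, b in anchor_spans
            ):  # cue inside an anchor phrase (e.g. "later") is not a finding
                continue
            if mention.category not in ("symptom", "location"):
                continue
            mention.status = assign_status(
                mention, masked_clause, cfg, clause_start=start, resolver=resolver
            )
            rec = record_at(mention.char_span[0])
            if mention.category == "symptom":
                rec.symptoms.append(mention)
            else:
                rec.locations.append(mention)
        dur = parse_duration(clause, cfg)
        if dur is not None:
            pos = start + (_duration_span(clause, cfg) or 0)
            rec = record_at(pos)
            if rec.episode_time is None:
                rec.episode_time = dur
        freq = parse_frequency(clause, cfg)
        if freq is not None:
            rec = record_at(start + clause.find(freq.raw))
            if rec.frequency is None:
                rec.frequency = freq
    return records


# ---------------------------------------------------------------------------
# JSON-Lines I/O


def read_documents(path: str | Path) -> list[dict]:
    """Read {"doc_id","text",...} objects from a JSON-Lines file."""
    docs = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                docs.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc.msg}") from exc
    return docs


def write_records(records: Iterable[SeizureRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_obj(), ensure_ascii=False) + "\n")


def read_records(path: str | Path) -> list[SeizureRecord]:
    with Path(path).open(encoding="utf-8") as fh:
        return [
            SeizureRecord.from_obj(json.loads(line))
            for line in fh
            if line.strip()
        ]
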