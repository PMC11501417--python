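"""Seizure-semiology lexicon: terms, synonyms, and surface-form indexing.

The lexicon is an application-ontology analogue: a flat dictionary of
terms (symptoms, seizure sites, cue words) with per-language canonical
labels and synonym lists, plus an optional ``parent_id`` hierarchy that
is carried as metadata only.  Extraction matches narrative text against
a :class:`SurfaceIndex` built from every label and synonym.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

CATEGORIES = frozenset(
    {
        "symptom",
        "location",
        "frequency_cue",
        "duration_cue",
        "negation_cue",
        "connective",
        "temporal_adverb",
    }
)


class LexiconError(ValueError):
    """Raised when a lexicon file violates a structural invariant."""


def _norm_char(c: str) -> str:
    # NFKC unifies full-width/half-width forms; only 1:1 mappings are
    # applied so character offsets into the raw text stay valid.
    n = unicodedata.normalize("NFKC", c)
    if len(n) != 1:
        n = c
    low = n.lower()
    return low if len(low) == 1 else n


def normalize_text(s: str) -> str:
    """Length-preserving normalization: full/half-width unification + lowercase."""
    return "".join(_norm_char(c) for c in s)


def normalize_surface(s: str) -> str:
    """Normalization for index keys and synonym deduplication (also trims)."""
    return normalize_text(s).strip()


@dataclass
class Term:
    """One lexicon entry.

    ``labels`` maps a language code to the canonical label; ``synonyms``
    maps a language code to alternative surface forms.  The canonical
    label always behaves as a synonym of itself during matching.
    """

    term_id: str
    labels: dict[str, str]
    synonyms: dict[str, list[str]] = field(default_factory=dict)
    category: str = "symptom"
    parent_id: str | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise LexiconError(
                f"term {self.term_id!r}: unknown category {self.category!r}"
            )
        # drop duplicate synonyms (after normalization) and synonyms that
        # collapse onto the canonical label
        for lang, syns in self.synonyms.items():
            label_key = normalize_surface(self.labels.get(lang, ""))
            seen: set[str] = set()
            deduped: list[str] = []
            for s in syns:
                key = normalize_surface(s)
                if not key or key == label_key or key in seen:
                    continue
                seen.add(key)
                deduped.append(s)
            self.synonyms[lang] = deduped

    def surfaces(self, language: str) -> list[str]:
        """Canonical label plus synonyms for ``language`` (label first)."""
        out: list[str] = []
        if language in self.labels:
            out.append(self.labels[language])
        out.extend(self.synonyms.get(language, []))
        return out


@dataclass
class Lexicon:
    name: str
    version: str
    languages: list[str]
    terms: dict[str, Term] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for tid, term in self.terms.items():
            if tid != term.term_id:
                raise LexiconError(f"term keyed {tid!r} has id {term.term_id!r}")
            if term.parent_id is not None and term.parent_id not in self.terms:
                raise LexiconError(
                    f"term {tid!r}: parent {term.parent_id!r} not in lexicon"
                )
        self._check_acyclic()
        for lang in self.languages:
            self._surface_map(lang)  # raises on collision

    def _check_acyclic(self) -> None:
        for tid in self.terms:
            seen = {tid}
            cur = self.terms[tid].parent_id
            while cur is not None:
                if cur in seen:
                    raise LexiconError(f"parent cycle through term {tid!r}")
                seen.add(cur)
                cur = self.terms[cur].parent_id

    def _surface_map(self, language: str) -> dict[str, tuple[str, str]]:
        entries: dict[str, tuple[str, str]] = {}
        for term in self.terms.values():
            for surface in term.surfaces(language):
                key = normalize_surface(surface)
                if not key:
                    continue
                prev = entries.get(key)
                if prev is not None and prev[0] != term.term_id:
                    raise LexiconError(
                        f"surface {surface!r} ({language}) claimed by terms "
                        f"{prev[0]!r} and {term.term_id!r}"
                    )
                entries.setdefault(key, (term.term_id, term.category))
        return entries

    def terms_of_category(self, category: str) -> list[Term]:
        return [t for t in self.terms.values() if t.category == category]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return (
            self.name == other.name
            and self.version == other.version
            and self.languages == other.languages
            and self.terms == other.terms
        )


@dataclass(frozen=True)
class SurfaceIndex:
    """Exact-match surface index for one language.

    ``entries`` maps the normalized surface to ``(term_id, category)``.
    ``lengths`` holds the distinct surface lengths, longest first, so a
    leftmost-longest scanner can probe only lengths that exist.
    """

    language: str
    entries: Mapping[str, tuple[str, str]]
    max_surface_length: int
    lengths: tuple[int, ...]

    def lookup(self, surface: str) -> tuple[str, str] | None:
        return self.entries.get(normalize_surface(surface))


def build_surface_index(lexicon: Lexicon, language: str) -> SurfaceIndex:
    """Index every canonical label and synonym of ``lexicon`` for ``language``."""
    if language not in lexicon.languages:
        raise LexiconError(f"language {language!r} not in lexicon {lexicon.name!r}")
    entries = lexicon._surface_map(language)
    if not entries:
        raise LexiconError(f"lexicon has no surfaces for language {language!r}")
    lengths = tuple(sorted({len(k) for k in entries}, reverse=True))
    return SurfaceIndex(
        language=language,
        entries=entries,
        max_surface_length=lengths[0],
        lengths=lengths,
    )


# ---------------------------------------------------------------------------
# synonym deduplication


def deduplicate_synonyms(
    raw_annotations: Sequence[tuple[str, str]],
    seed_mapping: Mapping[str, str],
) -> tuple[dict[str, set[str]], list[tuple[str, str]]]:
    """Collapse raw annotated surfaces onto canonical terms.

    ``raw_annotations`` is a list of ``(surface, language)`` pairs as they
    came off manual annotation; ``seed_mapping`` maps a *normalized*
    surface to a canonical term id.  Every raw surface lands in exactly
    one synonym set; surfaces with no seed entry are returned in a
    residual list for manual review.
    """
    if not raw_annotations:
        raise ValueError("raw_annotations must be non-empty")
    seed = {normalize_surface(k): v for k, v in seed_mapping.items()}
    groups: dict[str, set[str]] = {}
    residual: list[tuple[str, str]] = []
    for surface, language in raw_annotations:
        key = normalize_surface(surface)
        term = seed.get(key)
        if term is None:
            residual.append((surface, language))
        else:
            groups.setdefault(term, set()).add(key)
    return groups, residual


# ---------------------------------------------------------------------------
# JSON dialect I/O


def _term_to_obj(term: Term) -> dict:
    obj = {
        "id": term.term_id,
        "labels": term.labels,
        "synonyms": term.synonyms,
        "category": term.category,
        "parent": term.parent_id,
    }
    if term.attributes:
        obj["attributes"] = term.attributes
    return obj


def _term_from_obj(obj: dict, where: str) -> Term:
    try:
        return Term(
            term_id=obj["id"],
            labels=dict(obj.get("labels", {})),
            synonyms={k: list(v) for k, v in obj.get("synonyms", {}).items()},
            category=obj.get("category", "symptom"),
            parent_id=obj.get("parent"),
            attributes=dict(obj.get("attributes", {})),
        )
    except KeyError as exc:
        raise LexiconError(f"{where}: missing field {exc}") from exc


def lexicon_from_obj(obj: dict) -> Lexicon:
    terms: dict[str, Term] = {}
    for i, tobj in enumerate(obj.get("terms", [])):
        term = _term_from_obj(tobj, f"terms[{i}]")
        if term.term_id in terms:
            raise LexiconError(f"duplicate term id {term.term_id!r}")
        terms[term.term_id] = term
    return Lexicon(
        name=obj.get("name", "lexicon"),
        version=obj.get("version", "0"),
        languages=list(obj.get("languages", [])),
        terms=terms,
    )


def lexicon_to_obj(lexicon: Lexicon) -> dict:
    return {
        "name": lexicon.name,
        "version": lexicon.version,
        "languages": lexicon.languages,
        "terms": [_term_to_obj(t) for t in lexicon.terms.values()],
    }


def load_lexicon(path: str | Path) -> Lexicon:
    """Load the JSON lexicon dialect; structural violations are fatal."""
    path = Path(path)
    try:
        with path.open(encoding="utf-8") as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise LexiconError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    return lexicon_from_obj(obj)


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(lexicon_to_obj(lexicon), fh, ensure_ascii=False, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# 4-column TSV for spreadsheet curation (id, lang, surface, category);
# the first surface listed for a (term, language) pair is the canonical label.


def export_tsv(lexicon: Lexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for term in lexicon.terms.values():
            for lang in lexicon.languages:
                for surface in term.surfaces(lang):
                    writer.writerow([term.term_id, lang, surface, term.category])


def import_tsv(
    path: str | Path, name: str = "lexicon", version: str = "0"
) -> Lexicon:
    rows: list[list[str]] = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise LexiconError(f"{path}: line {lineno}: expected 4 columns")
            rows.append(row)
    terms: dict[str, Term] = {}
    languages: list[str] = []
    for term_id, lang, surface, category in rows:
        if lang not in languages:
            languages.append(lang)
        term = terms.get(term_id)
        if term is None:
            term = Term(term_id=term_id, labels={}, synonyms={}, category=category)
            terms[term_id] = term
        elif term.category != category:
            raise LexiconError(
                f"term {term_id!r}: conflicting categories "
                f"{term.category!r} and {category!r}"
            )
        if lang not in term.labels:
            term.labels[lang] = surface
        else:
            term.synonyms.setdefault(lang, []).append(surface)
    lex = Lexicon(name=name, version=version, languages=languages, terms=terms)
    return lex
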