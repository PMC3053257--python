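"""Dictionary-based concept tagging of phenotype phrases.

This is the stand-in for MetaMap/UMLS annotation: a lexicon maps surface
forms (possibly multi-word) to concept ids, preferred names and semantic
types.  Tagging is greedy longest-match, left to right and
case-insensitive; matched spans collapse into single tokens.  Concepts
whose semantic types are all in the ignored list are discarded (their
words stay unannotated).  Each kept concept is assigned one of four rough
semantic roles — Pathology, Anatomy, NamedEntity, Modifier — with the
fixed priority Pathology > Anatomy > NamedEntity > Modifier when a
concept carries types mapped to several roles.  Words not covered by the
lexicon fall back to a small deterministic part-of-speech tagger.

Precomputed annotations from a real concept-recognition system can be
substituted by building :class:`LexiconEntry` rows from its output
(see :func:`read_lexicon` / :func:`read_annotations`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "LexiconEntry",
    "RoleTable",
    "Token",
    "TaggedPhrase",
    "ROLE_PRIORITY",
    "tag_phrase",
    "rough_role",
    "normalize_surface",
    "pos_tag",
    "read_lexicon",
    "read_annotations",
    "load_role_table",
    "default_role_table",
    "default_example_lexicon",
]

ROLE_PRIORITY = ("Pathology", "Anatomy", "NamedEntity", "Modifier")

POS_TAGSET = frozenset({"NN", "JJ", "IN", "CC", "DT", "RB", "VB"})


@dataclass(frozen=True)
class LexiconEntry:
    """One concept: its surface forms, id, preferred name and semantic types."""

    surface_forms: tuple[str, ...]
    concept_id: str
    preferred_name: str
    semantic_types: frozenset[str]

    def __post_init__(self) -> None:
        if not self.surface_forms:
            raise ValueError("lexicon entry needs at least one surface form")
        if not self.concept_id:
            raise ValueError("lexicon entry needs a concept_id")


@dataclass(frozen=True)
class RoleTable:
    """Semantic-type -> rough-role mapping plus the allowed/ignored type sets."""

    role_of_type: dict[str, str]
    ignored_types: frozenset[str]

    @property
    def allowed_types(self) -> frozenset[str]:
        return frozenset(self.role_of_type)

    def validate(self) -> None:
        overlap = self.allowed_types & self.ignored_types
        if overlap:
            raise ValueError(f"types both allowed and ignored: {sorted(overlap)}")
        bad = set(self.role_of_type.values()) - set(ROLE_PRIORITY)
        if bad:
            raise ValueError(f"unknown role(s): {sorted(bad)}")


class Unmappable(Exception):
    """No allowed semantic type: the concept cannot receive a rough role."""


def rough_role(semantic_types: Iterable[str], roles: RoleTable) -> str:
    """Rough role of a concept under the fixed Pathology-first priority."""
    mapped = {roles.role_of_type[t] for t in semantic_types if t in roles.role_of_type}
    for role in ROLE_PRIORITY:
        if role in mapped:
            return role
    raise Unmappable(f"no allowed semantic type among {sorted(set(semantic_types))}")


@dataclass(frozen=True)
class Annotation:
    concept_id: str
    preferred_name: str
    semantic_types: frozenset[str]
    rough_role: str


@dataclass(frozen=True)
class Token:
    """One phrase token: either a concept span or a POS-tagged word."""

    surface: str
    annotation: Optional[Annotation] = None
    pos_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.annotation is None) == (self.pos_tag is None):
            raise ValueError("token needs exactly one of annotation or pos_tag")

    @property
    def label(self) -> str:
        """Grammar terminal: the rough role, or the POS tag."""
        return self.annotation.rough_role if self.annotation else self.pos_tag  # type: ignore[return-value]


@dataclass(frozen=True)
class TaggedPhrase:
    raw_text: str
    tokens: tuple[Token, ...]
    areas: frozenset[int] = frozenset()
    negated: bool = False

    def with_areas(self, areas: Iterable[int]) -> "TaggedPhrase":
        return replace(self, areas=frozenset(areas))

    def with_negated(self, negated: bool) -> "TaggedPhrase":
        return replace(self, negated=negated)


# --- part-of-speech fallback -------------------------------------------------

_CLOSED_CLASS = {
    "IN": {"of", "in", "on", "at", "with", "without", "by", "for", "from", "to",
           "into", "during", "under", "over", "after", "before", "due"},
    "CC": {"and", "or", "nor", "but", "plus"},
    "DT": {"the", "a", "an", "no", "this", "that", "these", "those", "some", "all", "both", "each"},
    "RB": {"not", "never", "especially", "usually", "often", "sometimes", "occasionally",
           "markedly", "mainly", "mostly", "very", "frequently", "rarely", "typically"},
    "VB": {"is", "are", "was", "were", "be", "been", "being", "has", "have", "had", "may", "can"},
}
_ADJ_WORDS = {
    "mild", "severe", "moderate", "normal", "abnormal", "increased", "decreased",
    "absent", "present", "large", "small", "short", "long", "broad", "narrow",
    "thick", "thin", "high", "low", "deep", "flat", "prominent", "sparse",
    "coarse", "fine", "early", "late", "delayed", "significant", "lower", "upper",
}
_ADJ_SUFFIXES = ("ic", "al", "ous", "ar", "ary", "ile", "oid", "ive", "ed", "ile")


def pos_tag(word: str) -> str:
    """Deterministic rule-based tag from {NN, JJ, IN, CC, DT, RB, VB}.

    The tagset follows the noun-phrase convention: anything not in a small
    closed-class or adjective lexicon is a noun (so e.g. "shows" is NN —
    phenotype phrases are treated as verbless noun phrases).
    """
    if not word:
        raise ValueError("word must be nonempty")
    w = word.lower().strip(".,;:()[]'\"")
    if not w:
        return "NN"
    for tag, words in _CLOSED_CLASS.items():
        if w in words:
            return tag
    if w in _ADJ_WORDS:
        return "JJ"
    if w.endswith("ly") and len(w) > 3:
        return "RB"
    if any(w.endswith(s) for s in _ADJ_SUFFIXES) and len(w) > 4:
        return "JJ"
    return "NN"


# --- tagging -----------------------------------------------------------------

def _word_key(word: str) -> str:
    return word.lower().strip(".,;:()[]'\"")


class _LexiconIndex:
    """Surface-form index keyed on normalized word sequences."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.by_words: dict[tuple[str, ...], list[LexiconEntry]] = {}
        self.max_len = 1
        for entry in entries:
            for form in entry.surface_forms:
                words = tuple(_word_key(w) for w in form.split())
                if not words:
                    continue
                self.by_words.setdefault(words, []).append(entry)
                self.max_len = max(self.max_len, len(words))
        for candidates in self.by_words.values():
            candidates.sort(key=lambda e: e.concept_id)


def tag_phrase(
    raw: str,
    lexicon: Iterable[LexiconEntry] | _LexiconIndex,
    roles: Optional[RoleTable] = None,
) -> TaggedPhrase:
    """Tag a phrase by greedy longest-match lexicon lookup.

    Ties between equally long candidate spans are broken by the
    lexicographically smallest concept id; candidates whose semantic types
    are all ignored (or none allowed) are discarded and their words remain
    unannotated with a POS tag instead.
    """
    if not raw.strip():
        raise ValueError("phrase must be nonempty")
    roles = roles if roles is not None else default_role_table()
    index = lexicon if isinstance(lexicon, _LexiconIndex) else _LexiconIndex(lexicon)
    words = raw.split()
    keys = [_word_key(w) for w in words]
    tokens: list[Token] = []
    i = 0
    while i < len(words):
        token = None
        for span in range(min(index.max_len, len(words) - i), 0, -1):
            key = tuple(keys[i : i + span])
            for entry in index.by_words.get(key, []):
                try:
                    role = rough_role(entry.semantic_types, roles)
                except Unmappable:
                    continue
                kept_types = frozenset(t for t in entry.semantic_types if t in roles.role_of_type)
                token = Token(
                    surface=" ".join(words[i : i + span]),
                    annotation=Annotation(entry.concept_id, entry.preferred_name, kept_types, role),
                )
                break
            if token is not None:
                i += span
                break
        if token is None:
            token = Token(surface=words[i], pos_tag=pos_tag(words[i]))
            i += 1
        tokens.append(token)
    return TaggedPhrase(raw_text=raw, tokens=tuple(tokens))


_FUNCTION_TAGS = frozenset({"IN", "DT", "CC", "VB"})


def normalize_surface(phrase: TaggedPhrase) -> str:
    """Canonical surface: preferred names of annotated tokens, in order.

    Function words (prepositions, determiners, conjunctions, copulas) are
    dropped; unannotated content words keep their lowercased surface.  A
    phrase with no annotated token at all falls back to its lowercased raw
    text, so normalization is total.
    """
    if not any(t.annotation for t in phrase.tokens):
        return phrase.raw_text.lower().strip()
    parts = []
    for token in phrase.tokens:
        if token.annotation:
            parts.append(token.annotation.preferred_name.lower())
        elif token.pos_tag not in _FUNCTION_TAGS:
            parts.append(_word_key(token.surface))
    return " ".join(p for p in parts if p)


# --- configuration loading ---------------------------------------------------

def read_lexicon(path: str | Path) -> list[LexiconEntry]:
    """Read a lexicon TSV: surface \\t concept_id \\t preferred_name \\t types(;-sep).

    Rows sharing a concept id are merged into one entry with all their
    surface forms.  Lines starting with ``#`` are comments.
    """
    merged: dict[str, dict] = {}
    for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
        surface, cui, preferred, types = (p.strip() for p in parts)
        slot = merged.setdefault(
            cui, {"forms": [], "preferred": preferred, "types": set()}
        )
        slot["forms"].append(surface.lower())
        slot["types"].update(t.strip() for t in types.split(";") if t.strip())
    return [
        LexiconEntry(tuple(dict.fromkeys(v["forms"])), cui, v["preferred"], frozenset(v["types"]))
        for cui, v in merged.items()
    ]


def read_annotations(path: str | Path) -> list[LexiconEntry]:
    """Import precomputed concept annotations (same TSV layout as the lexicon).

    Provided so output of an external annotator (e.g. a MetaMap run) can be
    dropped in as the tagging dictionary.
    """
    return read_lexicon(path)


def load_role_table(path: str | Path) -> RoleTable:
    return _parse_roles(Path(path).read_text("utf-8"), str(path))


def _parse_roles(text: str, source: str) -> RoleTable:
    role_of_type: dict[str, str] = {}
    ignored: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        head, _, rest = line.partition(":")
        types = [t.strip() for t in rest.split(";") if t.strip()]
        if head.startswith("role "):
            role = head[len("role "):].strip()
            if role not in ROLE_PRIORITY:
                raise ValueError(f"{source}:{lineno}: unknown role {role!r}")
            for t in types:
                role_of_type.setdefault(t, role)
        elif head.strip() == "ignore":
            ignored.update(types)
        else:
            raise ValueError(f"{source}:{lineno}: expected 'role <Name>:' or 'ignore:'")
    table = RoleTable(role_of_type, frozenset(ignored))
    table.validate()
    return table


def default_role_table() -> RoleTable:
    text = resources.files("phenonorm.data").joinpath("roles.cfg").read_text("utf-8")
    return _parse_roles(text, "roles.cfg")


def default_example_lexicon() -> list[LexiconEntry]:
    """The packaged fixture lexicon used by the worked examples."""
    with resources.as_file(resources.files("phenonorm.data").joinpath("example_lexicon.tsv")) as p:
        return read_lexicon(p)
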