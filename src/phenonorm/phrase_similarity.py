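"""Pairwise phrase similarity and synonym clustering within an area.

Two parsed phrases are similar when their parse trees agree on the
anchors, in this order: the Pathology (or NamedEntity) head terms must
match for anything else to be compared; then the Anatomy terms must
match (or be absent in both); then the modifiers must be synonymous.
Concept-annotated nodes are compared by concept id (CUI), unannotated
ones by case-insensitive string equality.  Phrases without a parse tree
are compared by whole-string Levenshtein distance with a maximum of 2.

Clusters are the connected components of the pairwise similarity graph
restricted to non-negated phrases of one area; singletons are discarded.
Single-linkage closure is deliberate: chains like the four
skull-ossification variants are synonymous as a group even though not
every pair matches directly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Protocol, Sequence

import edlib
import networkx as nx

from .area_mapper import MISC_AREA
from .phrase_parser import ParseTree

__all__ = [
    "PhraseCluster",
    "AnalyzedPhraseLike",
    "edit_distance",
    "similar_unparsed",
    "similar_parsed",
    "cluster_area",
    "load_modifier_synonyms",
    "default_modifier_synonyms",
    "MAX_EDIT_DISTANCE",
]

MAX_EDIT_DISTANCE = 2


# --- edit distance -----------------------------------------------------------

def edit_distance(a: str, b: str) -> int:
    """Case-insensitive character-level Levenshtein distance (unit costs)."""
    a, b = a.lower(), b.lower()
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def _normalize_for_distance(text: str) -> str:
    return " ".join(text.lower().split())


def similar_unparsed(a: str, b: str) -> bool:
    """String-rule similarity: Levenshtein distance at most 2."""
    return edit_distance(_normalize_for_distance(a), _normalize_for_distance(b)) <= MAX_EDIT_DISTANCE


# --- tree-rule similarity ----------------------------------------------------

_CORE_LABELS = ("PathologyNounPhrase", "EntityPhrase")
_HEAD_LEAF_LABELS = frozenset({"Pathology", "NamedEntity"})


def _maximal_cores(tree: ParseTree) -> list[ParseTree]:
    cores: list[ParseTree] = []

    def walk(node: ParseTree) -> None:
        if node.label in _CORE_LABELS:
            cores.append(node)
            return
        for child in node.children:
            walk(child)

    walk(tree)
    return cores


def _leaf_key(leaf: ParseTree) -> str:
    token = leaf.token
    if token is not None and token.annotation is not None:
        return token.annotation.concept_id
    return leaf.token.surface.lower() if leaf.token else ""


@dataclass(frozen=True)
class _TreeSignature:
    heads: frozenset[str]
    anatomy: frozenset[str]
    compound_residue: frozenset[str]
    modifiers: frozenset[str]


def _modifier_key(leaf: ParseTree, synonyms: Mapping[str, str]) -> str:
    token = leaf.token
    names = []
    if token is not None:
        if token.annotation is not None:
            names.append(token.annotation.preferred_name.lower())
        names.append(token.surface.lower())
    for name in names:
        if name in synonyms:
            return f"grp:{synonyms[name]}"
    if token is not None and token.annotation is not None:
        return token.annotation.concept_id
    return names[-1] if names else ""


def _signature(tree: ParseTree, synonyms: Mapping[str, str]) -> _TreeSignature:
    heads: set[str] = set()
    anatomy: set[str] = set()
    residue: set[str] = set()
    for core in _maximal_cores(tree):
        for leaf in core.leaves():
            if leaf.label in _HEAD_LEAF_LABELS:
                heads.add(_leaf_key(leaf))
            elif leaf.label == "Anatomy":
                anatomy.add(_leaf_key(leaf))
            elif leaf.label == "NN":
                residue.add(_leaf_key(leaf))
    # modifiers are collected over the whole tree: postposed modifiers
    # ("radius bowing, mild") attach above the core constituent
    modifiers = {
        _modifier_key(leaf, synonyms)
        for leaf in tree.leaves()
        if leaf.label in ("Modifier", "JJ")
    }
    return _TreeSignature(
        frozenset(heads), frozenset(anatomy), frozenset(residue), frozenset(modifiers)
    )


def similar_parsed(
    a: ParseTree,
    b: ParseTree,
    modifier_synonyms: Optional[Mapping[str, str]] = None,
) -> bool:
    """Tree-rule similarity of two complete parses.

    Gated comparison: both trees must have matching, nonempty
    Pathology/NamedEntity head terms; then the Anatomy terms, leftover
    noun-compound words inside the head constituent, and the modifier sets
    (under the synonym table) must all match.
    """
    synonyms = modifier_synonyms if modifier_synonyms is not None else default_modifier_synonyms()
    sig_a = _signature(a, synonyms)
    sig_b = _signature(b, synonyms)
    if not sig_a.heads or sig_a.heads != sig_b.heads:
        return False
    return (
        sig_a.anatomy == sig_b.anatomy
        and sig_a.compound_residue == sig_b.compound_residue
        and sig_a.modifiers == sig_b.modifiers
    )


# --- clustering --------------------------------------------------------------

class AnalyzedPhraseLike(Protocol):
    """What cluster_area needs from an analyzed phrase."""

    text: str
    surface: str  # normalized surface form
    areas: frozenset[int]
    tree: Optional[ParseTree]
    negated: bool


@dataclass(frozen=True)
class PhraseCluster:
    """An area-scoped synonym group with a canonical representative."""

    cluster_id: str
    area_id: int
    members: frozenset[str]
    representative: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 members")


def _slug(text: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", text.lower()).strip("-") or "x"


def cluster_area(
    phrases: Sequence[AnalyzedPhraseLike],
    area_id: int,
    modifier_synonyms: Optional[Mapping[str, str]] = None,
) -> list[PhraseCluster]:
    """Cluster the (non-negated, distinct) phrases of one area.

    Pairs where both phrases parsed are compared with the tree rule;
    pairs with at least one unparsed phrase fall back to the string rule.
    Clusters are connected components with at least two members.
    """
    if area_id == MISC_AREA:
        raise ValueError("the Misc area is not clustered")
    synonyms = modifier_synonyms if modifier_synonyms is not None else default_modifier_synonyms()
    distinct: dict[str, AnalyzedPhraseLike] = {}
    for p in phrases:
        if area_id not in p.areas:
            raise ValueError(f"phrase {p.text!r} does not belong to area {area_id}")
        if p.negated:
            continue
        distinct.setdefault(p.text, p)

    texts = sorted(distinct)
    graph = nx.Graph()
    graph.add_nodes_from(texts)
    sigs = {
        t: _signature(distinct[t].tree, synonyms) if distinct[t].tree is not None else None
        for t in texts
    }
    for i, ta in enumerate(texts):
        for tb in texts[i + 1 :]:
            sa, sb = sigs[ta], sigs[tb]
            if sa is not None and sb is not None:
                hit = bool(sa.heads) and sa.heads == sb.heads and (
                    sa.anatomy == sb.anatomy
                    and sa.compound_residue == sb.compound_residue
                    and sa.modifiers == sb.modifiers
                )
            else:
                hit = similar_unparsed(ta, tb)
            if hit:
                graph.add_edge(ta, tb)

    clusters: list[PhraseCluster] = []
    seen_ids: dict[str, int] = {}
    for component in sorted(nx.connected_components(graph), key=lambda c: min(c)):
        if len(component) < 2:
            continue
        representative = min(distinct[t].surface for t in component)
        base = f"c{area_id:02d}-{_slug(representative)}"
        n = seen_ids.get(base, 0)
        seen_ids[base] = n + 1
        cluster_id = base if n == 0 else f"{base}-{n + 1}"
        clusters.append(
            PhraseCluster(cluster_id, area_id, frozenset(component), representative)
        )
    return clusters


# --- modifier synonym table --------------------------------------------------

def _parse_modifier_synonyms(text: str) -> dict[str, str]:
    table: dict[str, str] = {}
    group = 0
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        terms = [t.strip().lower() for t in line.split(";") if t.strip()]
        if len(terms) < 2:
            raise ValueError(f"modifier synonym group needs >= 2 terms: {line!r}")
        group += 1
        for term in terms:
            table.setdefault(term, str(group))
    return table


def load_modifier_synonyms(path: str | Path) -> dict[str, str]:
    """Load a modifier-synonym table (one ';'-separated group per line)."""
    return _parse_modifier_synonyms(Path(path).read_text("utf-8"))


def default_modifier_synonyms() -> dict[str, str]:
    text = resources.files("phenonorm.data").joinpath("modifier_synonyms.cfg").read_text("utf-8")
    return _parse_modifier_synonyms(text)
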