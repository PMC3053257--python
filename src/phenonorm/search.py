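"""Cluster-expanded phenotype search over an analyzed corpus.

A query is matched by case-insensitive substring against every cluster
member and every unclustered phrase; a hit on any member of a cluster
returns the whole cluster, so all surface variants of a phenotype
retrieve the syndromes that mention any of them.  Selected features are
accumulated into a query vector and syndromes are ranked by cosine
similarity.  Phrases in negative context carry no feature, so a
syndrome whose only match for the query is a negation is never
retrieved; negated phrase hits are still reported, marked, for display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .corpus_io import ClinicalSynopsisRecord
from .phrase_similarity import PhraseCluster
from .pipeline import AnalyzedPhrase, Pipeline
from .syndrome_similarity import PhenotypeVector, build_vectors, cosine, phrase_feature, _membership

__all__ = ["QueryMatch", "SearchHit", "SearchIndex", "Session", "build_index", "expand_query", "search_syndromes"]

NEG_MARKER = "[NEG]"


@dataclass(frozen=True)
class QueryMatch:
    """One query-expansion result: a whole cluster or a single phrase."""

    kind: str  # "cluster" | "phrase"
    feature: Optional[str]  # None for negated phrase hits (display only)
    label: str  # representative (clusters) or the phrase text
    members: tuple[str, ...]
    negated: bool = False

    def display(self) -> str:
        prefix = f"{NEG_MARKER} " if self.negated else ""
        if self.kind == "cluster":
            return f"{prefix}{self.label}  [cluster: {'; '.join(self.members)}]"
        return f"{prefix}{self.label}"


@dataclass(frozen=True)
class SearchHit:
    record_id: str
    name: str
    cosine: float
    matched_features: frozenset[str]


@dataclass
class SearchIndex:
    """Persistable search artifact: vectors, clusters and phrase table."""

    records: dict[str, str]  # record_id -> name
    vectors: dict[str, frozenset[str]]
    clusters: list[PhraseCluster]
    phrases: list[dict]  # record_id, text, areas, negated, feature

    def to_json(self) -> str:
        return json.dumps(
            {
                "records": self.records,
                "vectors": {rid: sorted(v) for rid, v in self.vectors.items()},
                "clusters": [
                    {
                        "cluster_id": c.cluster_id,
                        "area_id": c.area_id,
                        "representative": c.representative,
                        "members": sorted(c.members),
                    }
                    for c in self.clusters
                ],
                "phrases": self.phrases,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SearchIndex":
        data = json.loads(text)
        return cls(
            records=data["records"],
            vectors={rid: frozenset(v) for rid, v in data["vectors"].items()},
            clusters=[
                PhraseCluster(
                    c["cluster_id"], c["area_id"], frozenset(c["members"]), c["representative"]
                )
                for c in data["clusters"]
            ],
            phrases=data["phrases"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SearchIndex":
        return cls.from_json(Path(path).read_text("utf-8"))


def build_index(
    records: Sequence[ClinicalSynopsisRecord],
    pipeline: Pipeline,
    analyzed: Optional[Sequence[AnalyzedPhrase]] = None,
    clusters: Optional[Sequence[PhraseCluster]] = None,
) -> SearchIndex:
    """Analyze a corpus once and freeze everything search needs."""
    if analyzed is None:
        analyzed = pipeline.analyze_corpus(records)
    if clusters is None:
        clusters = pipeline.build_clusters(analyzed)
    membership = _membership(clusters)
    vectors = build_vectors(analyzed, clusters)
    phrases = [
        {
            "record_id": p.record_id,
            "text": p.text,
            "areas": sorted(p.areas),
            "negated": p.negated,
            "feature": phrase_feature(p, membership),
            "is_name": p.is_name,
        }
        for p in analyzed
    ]
    return SearchIndex(
        records={r.record_id: r.name for r in records},
        vectors={rid: vec.features for rid, vec in vectors.items()},
        clusters=list(clusters),
        phrases=phrases,
    )


def _tightness(query: str, candidate: str) -> int:
    q, c = query.lower().strip(), candidate.lower()
    if q == c:
        return 0
    if c.startswith(q):
        return 1
    if q in c:
        return 2
    return 3


def expand_query(text: str, index: SearchIndex) -> list[QueryMatch]:
    """Clusters and unclustered phrases matching the query substring.

    A cluster matches if any member matches; results are ordered by match
    tightness (exact > prefix > substring), then alphabetically.  Negated
    phrase hits are returned flagged (and carry no selectable feature).
    """
    if not text.strip():
        raise ValueError("query must be nonempty")
    matches: list[tuple[int, str, QueryMatch]] = []
    clustered_texts = {m for c in index.clusters for m in c.members}
    for cluster in index.clusters:
        ranks = [_tightness(text, m) for m in cluster.members]
        best = min(ranks)
        if best < 3:
            matches.append(
                (
                    best,
                    cluster.representative,
                    QueryMatch(
                        "cluster",
                        cluster.cluster_id,
                        cluster.representative,
                        tuple(sorted(cluster.members)),
                    ),
                )
            )
    seen_phrases: set[tuple[str, bool]] = set()
    for p in index.phrases:
        if p["text"] in clustered_texts and not p["negated"]:
            continue
        key = (p["text"], p["negated"])
        if key in seen_phrases:
            continue
        rank = _tightness(text, p["text"])
        if rank < 3:
            seen_phrases.add(key)
            matches.append(
                (
                    rank,
                    p["text"],
                    QueryMatch(
                        "phrase",
                        None if p["negated"] else p["feature"],
                        p["text"],
                        (p["text"],),
                        negated=p["negated"],
                    ),
                )
            )
    matches.sort(key=lambda item: (item[0], item[1], item[2].kind))
    return [m for _, _, m in matches]


def search_syndromes(
    selected: Sequence[str], index: SearchIndex
) -> list[SearchHit]:
    """Rank syndromes by cosine against the selected feature set.

    Only syndromes sharing at least one selected feature are returned;
    ties are broken by record id.  Features exist only for non-negated
    phrases, so negation-only matches are excluded by construction.
    """
    query = frozenset(f for f in selected if f)
    if not query:
        raise ValueError("at least one selected feature is required")
    hits = []
    for rid in sorted(index.vectors):
        vec = index.vectors[rid]
        value = cosine(query, vec)
        if value > 0:
            hits.append(SearchHit(rid, index.records.get(rid, ""), value, query & vec))
    hits.sort(key=lambda h: (-h.cosine, h.record_id))
    return hits


class Session:
    """Incremental search: accumulate cluster selections across queries."""

    def __init__(self, index: SearchIndex):
        self.index = index
        self.selections: dict[str, QueryMatch] = {}
        self.last_matches: list[QueryMatch] = []

    def search(self, text: str) -> list[QueryMatch]:
        self.last_matches = expand_query(text, self.index)
        return self.last_matches

    def select(self, match_number: int) -> QueryMatch:
        """Select result ``match_number`` (1-based) of the last search."""
        if not 1 <= match_number <= len(self.last_matches):
            raise IndexError(f"no match number {match_number}")
        match = self.last_matches[match_number - 1]
        if match.feature is None:
            raise ValueError("a negated phrase cannot be selected")
        self.selections[match.feature] = match
        return match

    def deselect(self, feature: str) -> None:
        self.selections.pop(feature, None)

    def rank(self) -> list[SearchHit]:
        if not self.selections:
            raise ValueError("no features selected yet")
        return search_syndromes(sorted(self.selections), self.index)
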