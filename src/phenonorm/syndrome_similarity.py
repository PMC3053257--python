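"""Cluster-normalized phenotype vectors and cosine similarity between syndromes.

Each syndrome is reduced to a binary bag of phenotype features: every
non-negated phrase contributes its synonym-cluster id when it belongs to
a cluster in one of its areas (first clustered area in area-id order),
and its normalized surface form (area-scoped) otherwise.  Misc-area-only
phrases are excluded by default, as are negated phrases.  Similarity is
the cosine over these binary vectors, |A∩B| / sqrt(|A|·|B|).

Replacing surface variants by one cluster id can only merge features, so
two syndromes describing a phenotype with different wording become
connected; `new_connections` enumerates the syndrome pairs that share a
feature after normalization but shared none before.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .area_mapper import MISC_AREA
from .corpus_io import ClinicalSynopsisRecord
from .phrase_similarity import PhraseCluster
from .pipeline import AnalyzedPhrase, Pipeline

__all__ = [
    "PhenotypeVector",
    "SimilarityResult",
    "NewConnection",
    "phrase_feature",
    "build_vectors",
    "normalize_syndrome",
    "cosine",
    "pairwise_similarities",
    "new_connections",
]


@dataclass(frozen=True)
class PhenotypeVector:
    """Binary bag of normalized phenotype feature ids for one syndrome."""

    record_id: str
    features: frozenset[str]


@dataclass(frozen=True)
class SimilarityResult:
    record_a: str
    record_b: str
    cosine: float
    shared_features: frozenset[str]


@dataclass(frozen=True)
class NewConnection:
    record_a: str
    record_b: str
    shared_features: frozenset[str]


def _membership(clusters: Iterable[PhraseCluster]) -> dict[tuple[int, str], str]:
    table: dict[tuple[int, str], str] = {}
    for cluster in clusters:
        for member in cluster.members:
            table.setdefault((cluster.area_id, member), cluster.cluster_id)
    return table


def phrase_feature(
    phrase: AnalyzedPhrase,
    membership: dict[tuple[int, str], str],
    include_misc: bool = False,
) -> Optional[str]:
    """Feature id for one phrase, or None when it contributes nothing.

    Negated phrases and (by default) Misc-only phrases are dropped.  The
    first clustered area in area-id order wins; unclustered phrases fall
    back to their normalized surface, scoped by their smallest area id.
    """
    if phrase.negated:
        return None
    areas = sorted(phrase.areas if include_misc else phrase.areas - {MISC_AREA})
    if not areas:
        return None
    for area_id in areas:
        cluster_id = membership.get((area_id, phrase.text))
        if cluster_id is not None:
            return cluster_id
    return f"s{areas[0]:02d}:{phrase.surface}"


def build_vectors(
    analyzed: Sequence[AnalyzedPhrase],
    clusters: Iterable[PhraseCluster] = (),
    include_misc: bool = False,
    include_names: bool = False,
) -> dict[str, PhenotypeVector]:
    """Phenotype vectors for every record appearing in the analysis."""
    membership = _membership(clusters)
    features: dict[str, set[str]] = {}
    for phrase in analyzed:
        features.setdefault(phrase.record_id, set())
        if phrase.is_name and not include_names:
            continue
        feature = phrase_feature(phrase, membership, include_misc)
        if feature is not None:
            features[phrase.record_id].add(feature)
    return {
        rid: PhenotypeVector(rid, frozenset(feats)) for rid, feats in features.items()
    }


def normalize_syndrome(
    record: ClinicalSynopsisRecord,
    clusters: Iterable[PhraseCluster],
    pipeline: Pipeline,
    include_misc: bool = False,
) -> PhenotypeVector:
    """Analyze one record and reduce it to its normalized phenotype vector."""
    analyzed = pipeline.analyze_corpus([record], include_names=False)
    return build_vectors(analyzed, clusters, include_misc)[record.record_id]


def cosine(a: PhenotypeVector | frozenset[str] | set[str], b) -> float:
    """Binary cosine similarity |A∩B| / sqrt(|A|·|B|); 0 for empty vectors."""
    fa = a.features if isinstance(a, PhenotypeVector) else frozenset(a)
    fb = b.features if isinstance(b, PhenotypeVector) else frozenset(b)
    if not fa or not fb:
        return 0.0
    return len(fa & fb) / math.sqrt(len(fa) * len(fb))


def pairwise_similarities(
    vectors: dict[str, PhenotypeVector], min_cosine: float = 0.0
) -> list[SimilarityResult]:
    """All record pairs with cosine above threshold, ordered by record ids."""
    out: list[SimilarityResult] = []
    rids = sorted(vectors)
    for i, ra in enumerate(rids):
        for rb in rids[i + 1 :]:
            value = cosine(vectors[ra], vectors[rb])
            if value > 0 and value >= min_cosine:
                shared = vectors[ra].features & vectors[rb].features
                out.append(SimilarityResult(ra, rb, value, frozenset(shared)))
    return out


def _connected_pairs(vectors: dict[str, PhenotypeVector]) -> dict[tuple[str, str], frozenset[str]]:
    by_feature: dict[str, list[str]] = {}
    for rid in sorted(vectors):
        for feature in vectors[rid].features:
            by_feature.setdefault(feature, []).append(rid)
    pairs: dict[tuple[str, str], set[str]] = {}
    for feature, rids in by_feature.items():
        for i, ra in enumerate(rids):
            for rb in rids[i + 1 :]:
                pairs.setdefault((ra, rb), set()).add(feature)
    return {pair: frozenset(feats) for pair, feats in pairs.items()}


def new_connections(
    analyzed: Sequence[AnalyzedPhrase],
    clusters: Iterable[PhraseCluster],
    include_misc: bool = False,
) -> list[NewConnection]:
    """Syndrome pairs connected only after cluster normalization.

    A pair is connected when it shares at least one feature.  The result
    is connected_after minus connected_before (before = vectors built
    with no clusters, i.e. raw normalized surfaces), ordered by record-id
    pair.
    """
    after = _connected_pairs(build_vectors(analyzed, clusters, include_misc))
    before = _connected_pairs(build_vectors(analyzed, (), include_misc))
    out = [
        NewConnection(ra, rb, after[(ra, rb)])
        for (ra, rb) in sorted(after)
        if (ra, rb) not in before
    ]
    return out
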