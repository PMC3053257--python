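"""End-to-end analysis pipeline: corpus -> tagged/parsed/flagged phrases -> clusters.

The :class:`Pipeline` bundles the resources every stage needs (concept
lexicon, role table, grammar, area table, modifier-synonym table) and
runs the stages in order for each phrase: area mapping, concept tagging,
chart parsing, negation detection.  Syndrome names are analyzed too and
assigned the dedicated name area (area 1) so that name variants can
cluster; the Misc area (26) is never clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import area_mapper, concept_tagger, negation, phrase_parser, phrase_similarity
from .area_mapper import AreaTable, MISC_AREA, SYNDROME_NAME_AREA
from .concept_tagger import LexiconEntry, RoleTable, TaggedPhrase, _LexiconIndex
from .corpus_io import ClinicalSynopsisRecord
from .phrase_parser import Grammar, ParseTree
from .phrase_similarity import PhraseCluster

__all__ = ["AnalyzedPhrase", "Pipeline", "example_pipeline"]


@dataclass(frozen=True)
class AnalyzedPhrase:
    """One phrase occurrence after every analysis stage."""

    record_id: str
    heading: str
    subheading: Optional[str]
    text: str
    ordinal: int
    areas: frozenset[int]
    tagged: TaggedPhrase
    tree: Optional[ParseTree]
    parse_status: str
    negated: bool
    negation_reason: str
    surface: str
    is_name: bool = False

    @property
    def instance_key(self) -> tuple[str, str, Optional[str], str, int]:
        return (self.record_id, self.heading, self.subheading, self.text, self.ordinal)


class Pipeline:
    """Shared analysis context; build once, reuse across corpora."""

    def __init__(
        self,
        lexicon: Iterable[LexiconEntry],
        roles: Optional[RoleTable] = None,
        grammar: Optional[Grammar] = None,
        area_table: Optional[AreaTable] = None,
        modifier_synonyms: Optional[dict[str, str]] = None,
    ):
        self.roles = roles if roles is not None else concept_tagger.default_role_table()
        self.grammar = grammar if grammar is not None else phrase_parser.default_grammar()
        self.area_table = area_table if area_table is not None else area_mapper.default_area_table()
        self.modifier_synonyms = (
            modifier_synonyms
            if modifier_synonyms is not None
            else phrase_similarity.default_modifier_synonyms()
        )
        self._lexicon_index = _LexiconIndex(lexicon)

    # --- single-phrase stages ---

    def analyze_text(
        self,
        text: str,
        areas: frozenset[int],
        record_id: str = "000000",
        heading: str = "-",
        subheading: Optional[str] = None,
        ordinal: int = 0,
        is_name: bool = False,
    ) -> AnalyzedPhrase:
        tagged = concept_tagger.tag_phrase(text, self._lexicon_index, self.roles)
        result = phrase_parser.parse_phrase(tagged, self.grammar)
        negated, reason = negation.detect_negation(tagged, result.tree)
        return AnalyzedPhrase(
            record_id=record_id,
            heading=heading,
            subheading=subheading,
            text=text,
            ordinal=ordinal,
            areas=areas,
            tagged=tagged.with_areas(areas).with_negated(negated),
            tree=result.tree,
            parse_status=result.status,
            negated=negated,
            negation_reason=reason,
            surface=concept_tagger.normalize_surface(tagged),
            is_name=is_name,
        )

    # --- corpus level ---

    def analyze_corpus(
        self, records: Sequence[ClinicalSynopsisRecord], include_names: bool = True
    ) -> list[AnalyzedPhrase]:
        analyzed: list[AnalyzedPhrase] = []
        for rec in records:
            if include_names:
                analyzed.append(
                    self.analyze_text(
                        rec.name,
                        frozenset({SYNDROME_NAME_AREA}),
                        record_id=rec.record_id,
                        heading="-name-",
                        is_name=True,
                    )
                )
            counts: dict[tuple, int] = {}
            for entry in rec.entries:
                key = (entry.heading, entry.subheading, entry.phrase)
                ordinal = counts.get(key, 0)
                counts[key] = ordinal + 1
                areas = frozenset(
                    area_mapper.map_to_areas(entry.heading, entry.subheading, self.area_table)
                )
                analyzed.append(
                    self.analyze_text(
                        entry.phrase,
                        areas,
                        record_id=rec.record_id,
                        heading=entry.heading,
                        subheading=entry.subheading,
                        ordinal=ordinal,
                    )
                )
        return analyzed

    def build_clusters(self, analyzed: Sequence[AnalyzedPhrase]) -> list[PhraseCluster]:
        """Cluster every area except Misc; a phrase mapped to several areas
        participates in each of them."""
        clusters: list[PhraseCluster] = []
        area_ids = sorted({a for p in analyzed for a in p.areas} - {MISC_AREA})
        for area_id in area_ids:
            in_area = [p for p in analyzed if area_id in p.areas]
            clusters.extend(
                phrase_similarity.cluster_area(in_area, area_id, self.modifier_synonyms)
            )
        return clusters

    def parse_rate(self, analyzed: Sequence[AnalyzedPhrase]) -> float:
        """Fraction of phrases (names excluded) with a complete parse."""
        phrases = [p for p in analyzed if not p.is_name]
        if not phrases:
            return 0.0
        return sum(1 for p in phrases if p.parse_status == "parsed") / len(phrases)


def example_pipeline() -> Pipeline:
    """Pipeline over the packaged fixture lexicon and default configs."""
    return Pipeline(concept_tagger.default_example_lexicon())
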