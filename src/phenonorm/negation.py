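"""Rule-based negation detection for phenotype phrases.

Two NegEx-style rules, checked in order:

1. *normal-rule* — the standalone word ``normal`` anywhere in the phrase
   (word-boundary match, so ``abnormal`` does not fire) marks a negation.
2. *no-pathology-rule* — the word ``no`` marks a negation only when the
   phrase's parse tree contains a Pathology node; "no" before a plain
   anatomical term ("no natal teeth") describes an absent structure, not
   a negated finding.

Phrases flagged negated are excluded from synonym clustering and from
syndrome similarity, and are marked distinctly in search output.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional

from .concept_tagger import TaggedPhrase
from .phrase_parser import ParseTree

__all__ = ["detect_negation", "NORMAL_CUES", "NO_CUES"]

#: default cue words; extensible via the detect_negation arguments
NORMAL_CUES = ("normal",)
NO_CUES = ("no",)


def _word_present(text: str, cues: Iterable[str]) -> bool:
    lowered = text.lower()
    return any(re.search(rf"\b{re.escape(cue)}\b", lowered) for cue in cues)


def _tree_has_pathology(tree: ParseTree) -> bool:
    return any(
        node.is_leaf and node.label == "Pathology" for node in tree.iter_nodes()
    )


def detect_negation(
    phrase: TaggedPhrase,
    tree: Optional[ParseTree] = None,
    normal_cues: Iterable[str] = NORMAL_CUES,
    no_cues: Iterable[str] = NO_CUES,
) -> tuple[bool, str]:
    """Return ``(negated, reason)`` with reason in
    {"normal-rule", "no-pathology-rule", "none"}.

    When no parse tree is available the ``no`` rule falls back to checking
    whether any token carries the Pathology rough role — a conservative
    approximation of the tree test for unparsed phrases.
    """
    if _word_present(phrase.raw_text, normal_cues):
        return True, "normal-rule"
    if _word_present(phrase.raw_text, no_cues):
        if tree is not None:
            if _tree_has_pathology(tree):
                return True, "no-pathology-rule"
        elif any(
            t.annotation is not None and t.annotation.rough_role == "Pathology"
            for t in phrase.tokens
        ):
            return True, "no-pathology-rule"
    return False, "none"
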