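"""Independent reference implementations used as test oracles.

These are deliberately naive (plain recursion, exhaustive enumeration)
and share no code with the package paths they check.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Sequence

from phenonorm.phrase_parser import Grammar, ParseTree


def levenshtein_oracle(a: str, b: str) -> int:
    """Textbook recursive Levenshtein distance with memoization."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        return min(d(i - 1, j) + 1, d(i, j - 1) + 1, d(i - 1, j - 1) + cost)

    return d(len(a), len(b))


def transitive_closure_clusters(items: Sequence[str], related) -> set[frozenset[str]]:
    """Components of the symmetric relation by naive closure iteration.

    ``related(a, b)`` is the pairwise predicate; singletons are dropped,
    mirroring the cluster contract.
    """
    groups: list[set[str]] = [{item} for item in items]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] and groups[j] and any(
                    related(a, b) for a in groups[i] for b in groups[j]
                ):
                    groups[i] |= groups[j]
                    groups[j] = set()
                    changed = True
    return {frozenset(g) for g in groups if len(g) >= 2}


def enumerate_derivations(labels: Sequence[str], grammar: Grammar) -> set[str]:
    """All complete derivations of a label sequence, as bracketed strings.

    Pure top-down recursion over (symbol, span) with a path guard against
    unary cycles; no chart, no memoization across spans.
    """

    def partitions(n_parts: int, i: int, j: int):
        if n_parts == 1:
            yield [(i, j)]
            return
        for k in range(i + 1, j - n_parts + 2):
            for rest in partitions(n_parts - 1, k, j):
                yield [(i, k)] + rest

    def derive(sym: str, i: int, j: int, path: frozenset) -> set[str]:
        out: set[str] = set()
        if j - i == 1 and sym == labels[i]:
            out.add(f"({sym}:{i})")
        if sym not in grammar.nonterminals:
            return out
        key = (sym, i, j)
        if key in path:
            return out
        path = path | {key}
        for prod in grammar.productions:
            if prod.lhs != sym or len(prod.rhs) > j - i:
                continue
            for spans in partitions(len(prod.rhs), i, j):
                parts = []
                ok = True
                for child_sym, (a, b) in zip(prod.rhs, spans):
                    sub = derive(child_sym, a, b, path)
                    if not sub:
                        ok = False
                        break
                    parts.append(sub)
                if not ok:
                    continue
                combos = [""]
                for sub in parts:
                    combos = [c + " " + s for c in combos for s in sorted(sub)]
                out.update(f"({sym}{c})" for c in combos)
        return out

    return derive(grammar.start, 0, len(labels), frozenset())


def tree_shape(tree: ParseTree, offset: int = 0) -> str:
    """Bracketed form comparable with enumerate_derivations output."""
    if tree.is_leaf:
        return f"({tree.label}:{offset})"
    parts = []
    pos = offset
    for child in tree.children:
        parts.append(tree_shape(child, pos))
        pos += len(child.leaves())
    return f"({tree.label} " + " ".join(parts) + ")"


def check_tree_derives(tree: ParseTree, grammar: Grammar) -> bool:
    """Independent recognizer: every internal node instantiates a production."""
    productions = {(p.lhs, p.rhs) for p in grammar.productions}
    for node in tree.iter_nodes():
        if node.is_leaf:
            if node.label not in grammar.terminals:
                return False
        else:
            rhs = tuple(child.label for child in node.children)
            if (node.label, rhs) not in productions:
                return False
    return True
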