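"""Bottom-up chart parsing of tagged phenotype phrases with a CFG.

Phrases are treated as verbless noun phrases.  The grammar terminals are
the token labels produced by the concept tagger: the four rough semantic
roles for annotated tokens and POS tags for everything else.  Parsing is
exhaustive bottom-up dynamic programming over spans; among multiple
complete parses a single tree is selected deterministically (most
concept-annotated leaves under Pathology/Anatomy constituents, then
fewest internal nodes, then the leftmost derivation in canonical rule
order).  Phrases longer than 11 tokens are not parsed at all — the
downstream similarity rules fall back to whole-string edit distance for
them — since chart parsing long, heavily ambiguous noun phrases is not
worth the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence

from .concept_tagger import POS_TAGSET, ROLE_PRIORITY, TaggedPhrase, Token

__all__ = [
    "Grammar",
    "GrammarError",
    "ParseTree",
    "ParseResult",
    "MAX_PARSE_TOKENS",
    "parse_phrase",
    "all_parses",
    "load_grammar",
    "default_grammar",
]

MAX_PARSE_TOKENS = 11
ROLE_TERMINALS = frozenset(ROLE_PRIORITY)
_TREE_ENUM_CAP = 20000


class GrammarError(ValueError):
    pass


@dataclass(frozen=True)
class Production:
    lhs: str
    rhs: tuple[str, ...]

    def __str__(self) -> str:
        return f"{self.lhs} -> {' '.join(self.rhs)}"


@dataclass(frozen=True)
class Grammar:
    nonterminals: frozenset[str]
    terminals: frozenset[str]
    productions: tuple[Production, ...]
    start: str

    def validate(self) -> None:
        declared = self.nonterminals | self.terminals
        for prod in self.productions:
            if not prod.rhs:
                raise GrammarError(f"empty right-hand side in {prod}")
            for sym in prod.rhs:
                if sym not in declared:
                    raise GrammarError(f"undeclared symbol {sym!r} in {prod}")
        if self.start not in self.nonterminals:
            raise GrammarError(f"start symbol {self.start!r} is not a nonterminal")


@dataclass(frozen=True)
class ParseTree:
    """Labeled tree; leaves carry the input tokens in order."""

    label: str
    children: tuple["ParseTree", ...] = ()
    token: Optional[Token] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["ParseTree"]:
        if self.is_leaf:
            return [self]
        out: list[ParseTree] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def tokens(self) -> list[Token]:
        return [leaf.token for leaf in self.leaves() if leaf.token is not None]

    def iter_nodes(self) -> Iterator["ParseTree"]:
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def n_internal(self) -> int:
        return sum(1 for node in self.iter_nodes() if not node.is_leaf)

    def to_sexpr(self) -> str:
        if self.is_leaf:
            surface = self.token.surface if self.token else ""
            return f"({self.label} {surface!r})"
        return f"({self.label} " + " ".join(c.to_sexpr() for c in self.children) + ")"


@dataclass(frozen=True)
class ParseResult:
    """Outcome of parsing one phrase: a tree, or why there is none."""

    tree: Optional[ParseTree]
    status: str  # "parsed" | "no-parse" | "length-skipped"

    @property
    def parsed(self) -> bool:
        return self.tree is not None


# --- grammar loading ---------------------------------------------------------

def _parse_grammar(text: str, source: str) -> Grammar:
    productions: list[Production] = []
    nonterminals: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "->" not in line:
            raise GrammarError(f"{source}:{lineno}: expected 'LHS -> SYM ...', got {line!r}")
        lhs, _, rhs = line.partition("->")
        lhs = lhs.strip()
        if not lhs or " " in lhs:
            raise GrammarError(f"{source}:{lineno}: bad left-hand side {lhs!r}")
        if lhs not in nonterminals:
            nonterminals.append(lhs)
        for alternative in rhs.split("|"):
            symbols = tuple(alternative.split())
            if not symbols:
                raise GrammarError(f"{source}:{lineno}: empty alternative")
            productions.append(Production(lhs, symbols))
    if not productions:
        raise GrammarError(f"{source}: no productions")
    nts = frozenset(nonterminals)
    terminals = frozenset(ROLE_TERMINALS | POS_TAGSET)
    for lineno_prod in productions:
        for sym in lineno_prod.rhs:
            if sym not in nts and sym not in terminals:
                # report with the production, the line is already consumed
                raise GrammarError(f"{source}: undeclared symbol {sym!r} in {lineno_prod}")
    grammar = Grammar(nts, terminals, tuple(productions), nonterminals[0])
    grammar.validate()
    return grammar


def load_grammar(path: str | Path) -> Grammar:
    """Load a grammar file (``LHS -> SYM SYM | SYM`` lines; ``#`` comments).

    The start symbol is the left-hand side of the first rule.
    """
    path = Path(path)
    return _parse_grammar(path.read_text("utf-8"), str(path))


def default_grammar() -> Grammar:
    text = resources.files("phenonorm.data").joinpath("grammar.cfg").read_text("utf-8")
    return _parse_grammar(text, "grammar.cfg")


# --- chart parsing -----------------------------------------------------------

def _build_chart(labels: Sequence[str], grammar: Grammar):
    """Passive-edge chart: (i, j, sym) -> list of (production, child spans).

    Spans are processed in increasing length; within a span, unary chains
    are iterated to a fixed point.  Derivations are stored as backpointers
    for later tree enumeration.
    """
    n = len(labels)
    chart: dict[tuple[int, int, str], list[tuple[Optional[Production], tuple]]] = {}
    for i, label in enumerate(labels):
        chart[(i, i + 1, label)] = [(None, ())]

    by_lhs: dict[str, list[Production]] = {}
    for prod in grammar.productions:
        by_lhs.setdefault(prod.lhs, []).append(prod)

    def splits(rhs: tuple[str, ...], i: int, j: int):
        """All ways to realize rhs over [i, j) from existing passive edges."""
        if not rhs:
            if i == j:
                yield ()
            return
        sym = rhs[0]
        min_rest = len(rhs) - 1  # every symbol spans >= 1 token
        for k in range(i + 1, j - min_rest + 1):
            if (i, k, sym) in chart:
                for rest in splits(rhs[1:], k, j):
                    yield ((i, k, sym),) + rest

    for length in range(1, n + 1):
        for i in range(0, n - length + 1):
            j = i + length
            changed = True
            while changed:  # fixed point for unary chains within the span
                changed = False
                for prod in grammar.productions:
                    for children in splits(prod.rhs, i, j):
                        key = (i, j, prod.lhs)
                        entry = (prod, children)
                        cell = chart.setdefault(key, [])
                        if entry not in cell:
                            cell.append(entry)
                            changed = True
    return chart


def _enumerate_trees(
    chart, key, tokens: Sequence[Token], budget: list[int], stack: frozenset
) -> list[ParseTree]:
    i, j, sym = key
    if key not in chart:
        return []
    if key in stack:  # unary cycle guard for pathological grammars
        return []
    stack = stack | {key}
    trees: list[ParseTree] = []
    for prod, children in chart[key]:
        if budget[0] <= 0:
            break
        if prod is None:
            trees.append(ParseTree(sym, token=tokens[i]))
            continue
        child_lists = []
        ok = True
        for child_key in children:
            subtrees = _enumerate_trees(chart, child_key, tokens, budget, stack)
            if not subtrees:
                ok = False
                break
            child_lists.append(subtrees)
        if not ok:
            continue
        for combo in _product(child_lists):
            if budget[0] <= 0:
                break
            budget[0] -= 1
            trees.append(ParseTree(sym, tuple(combo)))
    return trees


def _product(lists):
    if not lists:
        yield ()
        return
    for head in lists[0]:
        for rest in _product(lists[1:]):
            yield (head,) + rest


def all_parses(phrase: TaggedPhrase, grammar: Optional[Grammar] = None) -> list[ParseTree]:
    """Every complete parse of the phrase (up to an enumeration cap), in
    canonical order (rule order, then split position)."""
    grammar = grammar if grammar is not None else default_grammar()
    tokens = phrase.tokens
    labels = [t.label for t in tokens]
    for label in labels:
        if label not in grammar.terminals:
            raise ValueError(f"token label {label!r} is not a grammar terminal")
    chart = _build_chart(labels, grammar)
    budget = [_TREE_ENUM_CAP]
    return _enumerate_trees(chart, (0, len(tokens), grammar.start), tokens, budget, frozenset())


def _annotated_core_leaves(tree: ParseTree) -> int:
    """Concept-annotated leaves dominated by a Pathology/Anatomy constituent."""
    count = 0

    def walk(node: ParseTree, inside: bool) -> None:
        nonlocal count
        inside = inside or node.label in ("PathologyNounPhrase", "AnatomyPhrase")
        if node.is_leaf:
            if inside and node.token is not None and node.token.annotation is not None:
                count += 1
            return
        for child in node.children:
            walk(child, inside)

    walk(tree, False)
    return count


def parse_phrase(phrase: TaggedPhrase, grammar: Optional[Grammar] = None) -> ParseResult:
    """Parse one tagged phrase; returns the selected tree or a skip flag.

    Phrases longer than ``MAX_PARSE_TOKENS`` (11 post-chunking tokens)
    return ``length-skipped``; unparseable phrases return ``no-parse``.
    """
    if len(phrase.tokens) > MAX_PARSE_TOKENS:
        return ParseResult(None, "length-skipped")
    trees = all_parses(phrase, grammar)
    if not trees:
        return ParseResult(None, "no-parse")
    best = min(
        range(len(trees)),
        key=lambda idx: (-_annotated_core_leaves(trees[idx]), trees[idx].n_internal(), idx),
    )
    return ParseResult(trees[best], "parsed")
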