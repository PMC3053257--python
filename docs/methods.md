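# Methods

This note records the model behind `phenonorm`, the parameters that
matter, the numerical and design choices made where the design was
genuinely open, and what the synthetic evaluation does and does not
demonstrate.

## Problem model

A clinical-synopsis corpus is a set of syndrome records, each an ordered
list of free-text noun phrases under heading/subheading context. The
package treats phenotype identity as an emergent property: rather than
mapping phrases into a fixed ontology (which loses every phrase the
ontology lacks), it computes pairwise similarity between phrases and
takes the connected components as synonym clusters, in the spirit of a
synset. Negation is modeled as a phrase-level flag, not a scoped
sub-span: clinical-synopsis phrases are short, verbless noun phrases,
and a flagged phrase is simply withheld from clustering and similarity.

## Pipeline stages and their parameters

**Area mapping.** 26 areas; matching is case-insensitive after
punctuation stripping and whitespace collapsing; a heading may map to
several areas ("Head and Neck" → Neck and Head); subheadings refine by
union; unmatched context falls into area 26 (Misc), which is never
clustered; area 1 is reserved for syndrome names. The packaged table is
a reconstruction keyed on the published area names — the full original
heading-to-area assignment was never published — and is fully
overridable (`areas.cfg` format).

**Concept tagging.** Greedy longest-match, left-to-right,
case-insensitive; ties between equal spans break on the smaller concept
id so tagging is a pure function of (phrase, lexicon, role table).
Concepts whose semantic types are all ignored (organizations, animals,
geography, ...) are dropped rather than mis-tagged; the allowed/ignored
type lists ship as editable config because the originals are not public.
A concept with types in several roles takes the highest-priority role
under Pathology > Anatomy > NamedEntity > Modifier — similarity anchors
on pathologies first, so that is the reading that keeps downstream
comparisons conservative. Surface normalization joins the preferred
names of annotated tokens (dropping function words, keeping unannotated
content words), which collapses inflection/plural/preposition variants
whenever the lexicon lists those surface forms.

**POS fallback.** A deterministic closed-class + suffix tagger over
{NN, JJ, IN, CC, DT, RB, VB}. Phrases are treated as verbless noun
phrases, so unknown words — including verb-looking ones like "shows" —
default to NN. The tagger is an interface; a trained tagger can be
substituted without touching anything downstream.

**Parsing.** The grammar is data (`grammar.cfg`), hand-built around the
structures phenotype phrases exhibit: attributive pathology
("brainstem hypoplasia"), prepositional attachment ("hypoplasia of the
brainstem"), modifier stacks, noun compounds, coordination. Chart
parsing is exhaustive bottom-up span DP with unary-chain fixpoints; all
complete parses are enumerated (capped at 20 000 trees) and one is
selected by (1) most concept-annotated leaves inside Pathology/Anatomy
constituents, (2) fewest internal nodes, (3) leftmost in canonical rule
order — a deterministic resolution of noun-phrase ambiguity ("altered
melatonin secretion" has two readings; some rule must pick one). The
11-token length cutoff is counted after chunking, since chunking
precedes parsing in this pipeline; skipped and unparseable phrases
remain first-class citizens of the string-distance comparison path.

**Negation.** Standalone "normal" (word-boundary regex, so "abnormal"
never fires) is checked before the "no"-plus-Pathology rule. For
phrases without a parse tree, the second rule falls back to token-level
roles — conservative, since a Pathology token in an unparsed "no ..."
phrase almost always heads it. Cue lists are arguments, defaulting to
exactly {"normal"} and {"no"}.

**Phrase similarity.** The tree rule is gated: no shared Pathology (or
NamedEntity) head, no comparison. Heads, anatomy terms and leftover
in-constituent nouns compare by concept id when annotated, else by
case-insensitive string — so a typo that escapes the lexicon blocks a
match instead of silently widening one. Modifier sets must correspond
under a small synonym table (`modifier_synonyms.cfg`); the notion of
"synonymous modifiers" is externalized to data because no principled
in-vocabulary definition exists. Modifier comparison uses Modifier-role
and JJ leaves over the whole tree but ignores adverbs: hedging adverbs
("especially") do not change which phenotype a phrase denotes.
Unparsed-vs-anything comparison is whole-phrase Levenshtein distance
(unit costs, case-insensitive, via edlib) with threshold 2 — enough for
typos and trivial inflection, too tight to bridge different anatomy.

**Clustering.** Single-linkage connected components (networkx) over the
pairwise relation, per area, negated phrases excluded, singletons
dropped. Single linkage is deliberate: synonym groups are chains (A ~ B
by modifier synonymy, B ~ C by anatomy merge) and the pathology gate
keeps chains from wandering across phenotypes. Cluster ids derive from
the lexicographically smallest normalized surface, so ids are stable
across runs.

**Vectors and similarity.** Binary presence/absence features, duplicates
collapsed — phrases rarely repeat within a record and no weighting
scheme is defensible from first principles. A phrase in several areas
contributes one feature (first clustered area in area-id order) to avoid
double counting. Misc-only phrases are excluded by default (they are
unclustered noise); syndrome-name pseudo-phrases participate in
clustering and search but not in phenotype vectors. Cosine is
|A∩B|/√(|A||B|), zero for empty vectors. Because normalization only
merges features and no generated record holds two variants of one base
phenotype, the cosine of any pair is non-decreasing under normalization;
a degenerate corpus in which one record carries two co-clustered
variants could violate this, which is why the monotonicity assertion is
made on generated corpora. "New connections" are the pairs sharing a
feature after normalization but none before (before = surface-normalized
vectors without cluster replacement).

**Search.** Substring expansion ordered exact > prefix > substring, then
alphabetically; selecting any match adds its feature to the session
vector; ranking is cosine over the union of selections with record-id
tie-breaks. Negated phrases surface in expansion with a `[NEG]` marker
but cannot be selected and never score.

## The synthetic generator

The generator is the study instrument, not a demo. Defaults: 50
syndromes, 200 base phenotypes, 3 surface variants per base, typo rate
0.05, negation rate 0.1, heading-inconsistency rate 0.05. Each base
phenotype is a (pathology stem, anatomy stem, optional modifier) triple
drawn from a packaged vocabulary of inflection pairs (bowing/bowed),
singular/plural pairs (radius/radii) and modifiers; variants instantiate
templates covering adjectival, prepositional ("X of the Y"), word-order
and plural forms; typos are 1–2 character edits (never fabricating a
negation cue); negations wrap instances as "no ..." or "... normal";
heading noise swaps a heading for an overlapping variant ("Limbs" vs
"Limb"). Every base appears in variants+1 records so all its variants
are realized, each record samples distinct bases, and everything is
driven by one seeded RNG, making corpora byte-reproducible.

What this emulates well: surface variability, negation forms, heading
drift, dictionary-miss behavior under typos. What it does not: real
corpora have richer syntax (lab phrases with stacked prepositions parse
poorly), genuinely ambiguous negations ("low to normal IQ"), semantic
synonymy absent from any lexicon, and concept annotators with their own
error modes. Passing the recovery bounds therefore shows the machinery
is correct and well-calibrated on clean-but-varied input; it does not
certify real-world precision figures.

## Evaluation and problem sizes

The recovery metrics score distinct non-negated phrase texts: pairwise
precision/recall of co-clustering against planted groups, negation
precision/recall over instances, and the parse rate. The default study
corpus (800 instances, ~570 distinct texts) analyzes in under a second;
test oracles run exhaustively where cheap (all string pairs to length 3
for edit distance, plus seeded samples to length 8; full derivation
enumeration for phrases ≤ 6 tokens; naive transitive closure on
~100-phrase areas) — sizes chosen so the whole suite stays interactive
while still exercising every code path.

## Known limitations

- The grammar, area table, semantic-type lists and modifier-synonym
  table are reconstructions shipped as data; users with better resources
  should override them.
- No word-sense disambiguation: the first (smallest-id) concept wins.
- Negation scope is phrase-level; "loss of vision in one eye only" style
  partial scopes are out of scope.
- Edit distance at threshold 2 can in principle link short unparsed
  phrases that differ meaningfully; in practice the parser handles
  nearly all short phrases, leaving the string path to typos and
  long/skipped phrases.
- Cross-area synonymy is intentionally not detected.
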