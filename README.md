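# phenonorm

Normalization, synonym clustering and similarity search over
clinical-synopsis phenotype phrases.

Catalogs of Mendelian syndromes describe each disease as a structured
list of free-text phenotype phrases grouped under headings ("Head",
"Limbs", "Labs", ...). The same phenotype is written many ways — "bowed
radius", "bowing of the radius", "bowed radii" — and absence is stated
in-line ("no dysarthria", "plasma testosterone is normal"). Both habits
defeat naive search and corrupt any similarity measure computed over
shared phrases. `phenonorm` addresses this for clinicians searching such
catalogs and for anyone mining them: it discovers clusters of synonymous
phrases, flags negations, and uses the normalized descriptions for
syndrome-to-syndrome similarity and for cluster-expanded search.

## The method

For every phrase, in order:

1. **Area mapping.** The heading/subheading context is mapped onto 26
   body-system areas (a total, case-insensitive rule table with a Misc
   fallback); phrases are only ever compared within an area.
2. **Concept tagging.** Greedy longest-match dictionary tagging against a
   concept lexicon (surface form → concept id, preferred name, semantic
   types) chunks multi-word concepts into single tokens and assigns each
   a rough semantic role — Pathology, Anatomy, NamedEntity or Modifier —
   with noisy semantic types filtered out. Unmatched words get a
   rule-based POS tag. This is a pluggable stand-in for a full medical
   concept annotator; precomputed annotations can be imported.
3. **Parsing.** A hand-written noun-phrase CFG is applied by bottom-up
   chart parsing over the token labels; phrases longer than 11 tokens are
   skipped. Tree selection among ambiguous parses is deterministic.
4. **Negation.** Two rules: standalone *normal* anywhere; *no* together
   with a Pathology node in the parse tree ("no dysarthria" is negated,
   "no natal teeth" is not). Negated phrases join no cluster and carry no
   similarity weight.
5. **Clustering.** Within each area, parsed phrases are similar when
   their trees agree on the Pathology head (gate), the Anatomy terms and
   the modifier sets (under a modifier-synonym table); concept-annotated
   nodes compare by concept id, others by case-insensitive string.
   Unparsed phrases compare by Levenshtein distance ≤ 2. Clusters are the
   connected components with ≥ 2 members.
6. **Similarity & search.** Each syndrome becomes a binary feature set
   (cluster ids, else normalized surfaces); similarity is the cosine
   |A∩B|/√(|A||B|). Queries expand through clusters (a hit on any member
   retrieves all variants) and never match phrases in negative context.

A synthetic-corpus generator plants ground-truth synonym groups
(inflection, preposition, word-order, plural and typo variants) and
negations, so the whole pipeline can be scored on recovery without any
licensed data.

## Worked example

```python
import phenonorm as pn

pipeline = pn.example_pipeline()   # packaged fixture lexicon + defaults
phrases = [pipeline.analyze_text(t, frozenset({19})) for t in [
    "ossification defect of skull",
    "absent ossification of skull vault",
    "decreased skull ossification",
    "deficient skull ossification",
]]
for cluster in pn.cluster_area(phrases, 19):
    print(cluster.cluster_id, sorted(cluster.members))
```

prints

```
c19-absent-ossification-skull ['absent ossification of skull vault',
 'decreased skull ossification', 'deficient skull ossification',
 'ossification defect of skull']
```

— all four wordings of deficient skull ossification land in one synonym
cluster: the first pair via the modifier-synonym group
(defect/absent/decreased/deficient) and the rest by transitive closure of
the tree rule. The `examples/` directory has one short script per
capability (tagging, parsing, negation, clustering, similarity, search,
and the synthetic study); each prints its results with a line on what
they mean. The same functionality is available from the shell:

```
phenonorm gen --seed 1 --out corpus.tsv --truth truth.tsv
phenonorm cluster --in corpus.tsv --out clusters.tsv
phenonorm index --in corpus.tsv --out index.json
phenonorm search --index index.json --query "thickened cranium"
phenonorm repl --index index.json
```

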