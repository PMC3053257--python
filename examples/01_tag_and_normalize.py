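"""Tag phenotype phrases with lexicon concepts and normalize their surface.

Shows how a dictionary tagger (the MetaMap stand-in) chunks multi-word
concepts, assigns rough semantic roles, and collapses surface variants
of one phenotype onto a single canonical string.
"""

import phenonorm as pn

lexicon = pn.default_example_lexicon()

tagged = pn.tag_phrase("brainstem hypoplasia", lexicon)
print("tokens of 'brainstem hypoplasia':")
for token in tagged.tokens:
    if token.annotation:
        a = token.annotation
        print(f"  {token.surface!r:14} -> {a.concept_id} ({a.rough_role}, {a.preferred_name})")
    else:
        print(f"  {token.surface!r:14} -> POS {token.pos_tag}")

print()
print("surface normalization of bowing-radius variants:")
for raw in ["bowed radius", "bowing of the radius", "bowing of radius", "bowed radii"]:
    print(f"  {raw!r:24} -> {pn.normalize_surface(pn.tag_phrase(raw, lexicon))!r}")

print()
print("All four variants normalize to one canonical form, 'bowing radius':")
print("inflection, prepositions and plural are handled by the lexicon's")
print("surface forms and preferred names, not by hard-coded rules.")
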