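# Default noun-phrase grammar over concept-tagged phenotype phrases.
# Terminals are the four rough roles (Pathology, Anatomy, NamedEntity,
# Modifier) plus POS tags (NN, JJ, IN, CC, DT, RB, VB). The start symbol
# is the first left-hand side (NP). The grammar was hand-built around the
# structures phenotype phrases actually exhibit (attributive pathology,
# "X of the Y" prepositional attachment, modifier stacks, noun compounds,
# coordination) and is shipped as data so it can be edited freely.

NP -> CORE
NP -> DT NP
NP -> NP CC NP
NP -> NounCompound NP
NP -> NP ModifierPhrase
NP -> ModifierPhrase NP

CORE -> PathologyNounPhrase
CORE -> AnatomyPhrase
CORE -> EntityPhrase
CORE -> NounCompound

PathologyNounPhrase -> Pathology
PathologyNounPhrase -> Anatomy PathologyNounPhrase
PathologyNounPhrase -> ModifierPhrase PathologyNounPhrase
PathologyNounPhrase -> PathologyNounPhrase PP
PathologyNounPhrase -> PathologyNounPhrase ModifierPhrase
PathologyNounPhrase -> Pathology AnatomyPhrase
PathologyNounPhrase -> Pathology NounCompound

AnatomyPhrase -> Anatomy
AnatomyPhrase -> ModifierPhrase AnatomyPhrase
AnatomyPhrase -> AnatomyPhrase PP

EntityPhrase -> NamedEntity
EntityPhrase -> ModifierPhrase EntityPhrase
EntityPhrase -> EntityPhrase PP

ModifierPhrase -> Modifier
ModifierPhrase -> JJ
ModifierPhrase -> RB
ModifierPhrase -> RB ModifierPhrase
ModifierPhrase -> Modifier ModifierPhrase
ModifierPhrase -> ModifierPhrase CC ModifierPhrase

PP -> IN NP
PP -> RB PP

NounCompound -> NN
NounCompound -> NN NounCompound
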