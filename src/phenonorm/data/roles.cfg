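# Semantic-type filter and rough-role mapping.
# Concepts are kept only if at least one of their semantic types is listed
# under a role; types listed under "ignore" are noise sources and any
# concept whose types are ALL ignored is dropped. The exact published
# lists were in unavailable supplementary material; these defaults follow
# the four documented rough roles (pathology/finding, anatomy, named
# entities, modifiers) and the documented ignore examples, and are fully
# user-overridable.
#
# Syntax:  role <RoleName>: type; type; ...
#          ignore: type; type; ...

role Pathology: Pathologic Function; Disease or Syndrome; Finding; Sign or Symptom; Congenital Abnormality; Anatomical Abnormality; Acquired Abnormality; Neoplastic Process; Mental or Behavioral Dysfunction; Cell or Molecular Dysfunction; Injury or Poisoning
role Anatomy: Body Part, Organ, or Organ Component; Body Location or Region; Body Space or Junction; Body System; Tissue; Embryonic Structure; Cell; Cell Component
role NamedEntity: Amino Acid, Peptide, or Protein; Organic Chemical; Pharmacologic Substance; Biologically Active Substance; Gene or Genome; Enzyme; Hormone; Vitamin; Carbohydrate; Lipid; Element, Ion, or Isotope; Bacterium; Virus; Fungus; Molecular Function; Physiologic Function; Organism Function; Organ or Tissue Function; Cell Function; Laboratory Procedure; Laboratory or Test Result
role Modifier: Qualitative Concept; Quantitative Concept; Spatial Concept; Temporal Concept; Functional Concept

ignore: Fish; Bird; Amphibian; Reptile; Mammal; Animal; Plant; Organization; Health Care Related Organization; Professional or Occupational Group; Geographic Area; Language; Occupational Activity; Governmental or Regulatory Activity; Conceptual Entity; Idea or Concept; Intellectual Product
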