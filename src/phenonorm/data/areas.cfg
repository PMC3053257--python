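# Default area table: 26 phenotype areas and heading -> area rules.
# The original heading/subheading-to-area assignment (159 distinct headings)
# was never published in full; this table reconstructs it from the area
# names and the documented examples, and is fully user-overridable.
#
# Syntax:
#   area <id> <name>
#   <heading pattern> [| <subheading pattern>] -> <area_id>[,<area_id>...]
# Patterns are matched case-insensitively after punctuation stripping and
# whitespace collapsing. Unmatched headings fall back to area 26 (Misc).

area 1 Syndrome names
area 2 Abdomen/gi
area 3 Respiratory
area 4 Gu/renal
area 5 Gu/genitalia
area 6 Cardiovascular
area 7 Muscle
area 8 Endo
area 9 Neuro
area 10 Oncology
area 11 Heme
area 12 Immune
area 13 Eyes
area 14 Face
area 15 Teeth
area 16 Neck
area 17 Head
area 18 Limb
area 19 Skel
area 20 Chest
area 21 Growth
area 22 Nails
area 23 Skin
area 24 Hair
area 25 Lab
area 26 Misc

growth -> 21
head and neck -> 16,17
head -> 17
neck -> 16
face -> 14
facies -> 14
ears -> 17
eyes -> 13
nose -> 14
mouth -> 14
teeth -> 15
dental -> 15
cardiovascular -> 6
heart -> 6
vascular -> 6
cardiac -> 6
respiratory -> 3
airways -> 3
lung -> 3
larynx -> 3
chest -> 20
thorax -> 20
ribs -> 20
abdomen -> 2
abdomen gi -> 2
gastrointestinal -> 2
liver -> 2
spleen -> 2
biliary tract -> 2
genitourinary -> 4,5
gu -> 4,5
gu renal -> 4
renal -> 4
kidneys -> 4
ureters -> 4
bladder -> 4
genitalia -> 5
external genitalia -> 5
internal genitalia -> 5
gu genitalia -> 5
skeletal -> 19
skel -> 19
skull -> 17,19
spine -> 19
pelvis -> 19
limbs -> 18
limb -> 18
hands -> 18
feet -> 18
skin -> 23
skin nails hair -> 22,23,24
nails -> 22
hair -> 24
muscle -> 7
muscle soft tissue -> 7
muscles -> 7
neurologic -> 9
neuro -> 9
central nervous system -> 9
peripheral nervous system -> 9
behavioral psychiatric manifestations -> 9
endocrine -> 8
endocrine features -> 8
metabolic features -> 8
hematology -> 11
heme -> 11
immunology -> 12
immune -> 12
oncology -> 10
neoplasia -> 10
laboratory abnormalities -> 25
labs -> 25
lab -> 25
miscellaneous -> 26
misc -> 26
inheritance -> 26
prenatal manifestations -> 26
voice -> 26
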