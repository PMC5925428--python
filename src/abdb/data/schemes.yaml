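# Variable-domain position tables for the Kabat, Chothia and Martin numbering schemes.
#
# Base position labels are shared between schemes: light 1..107, heavy 1..82,82A,82B,82C,83..113.
# The schemes differ in where extra (inserted) residues receive insertion codes: Kabat places
# CDR-L1 insertions after 27 and CDR-H1 insertions after 35, Chothia and Martin place them at
# the structurally correct 30 / 31; Martin additionally anchors heavy FR3 framework insertions
# at 72. CDR ranges are given under both the Kabat and Chothia definitions; the pipeline's
# contact rules use the Kabat definition by default.
#
# `anchors` are conserved framework positions used to decide whether an alignment to the
# template is an antibody at all: numbering fails cleanly when fewer than half of them carry
# the template residue.

base_labels:
  L: ["1-107"]
  H: ["1-82", "82A", "82B", "82C", "83-113"]

regions:
  L:
    - {name: FR-L1,  start: 1,  end: 23}
    - {name: CDR-L1, start: 24, end: 34}
    - {name: FR-L2,  start: 35, end: 49}
    - {name: CDR-L2, start: 50, end: 56}
    - {name: FR-L3,  start: 57, end: 88}
    - {name: CDR-L3, start: 89, end: 97}
    - {name: FR-L4,  start: 98, end: 107}
  H:
    - {name: FR-H1,  start: 1,  end: 30}
    - {name: CDR-H1, start: 31, end: 35}
    - {name: FR-H2,  start: 36, end: 49}
    - {name: CDR-H2, start: 50, end: 65}
    - {name: FR-H3,  start: 66, end: 94}
    - {name: CDR-H3, start: 95, end: 102}
    - {name: FR-H4,  start: 103, end: 113}

# Insertion anchor per region and scheme: extra residues in that region get insertion
# codes (A, B, ...) on this base position. Regions not listed attach insertions to the
# base position preceding the alignment's gap.
insertion_anchors:
  kabat:
    L: {CDR-L1: 27, CDR-L2: 54, CDR-L3: 95, FR-L4: 106}
    H: {CDR-H1: 35, CDR-H2: 52, CDR-H3: 100}
  chothia:
    L: {CDR-L1: 30, CDR-L2: 54, CDR-L3: 95, FR-L4: 106}
    H: {CDR-H1: 31, CDR-H2: 52, CDR-H3: 100}
  martin:
    L: {CDR-L1: 30, CDR-L2: 54, CDR-L3: 95, FR-L4: 106}
    H: {CDR-H1: 31, CDR-H2: 52, CDR-H3: 100, FR-H3: 72}

cdr_definitions:
  kabat:
    L: {CDR-L1: [24, 34], CDR-L2: [50, 56], CDR-L3: [89, 97]}
    H: {CDR-H1: [31, 35], CDR-H2: [50, 65], CDR-H3: [95, 102]}
  chothia:
    L: {CDR-L1: [26, 32], CDR-L2: [50, 52], CDR-L3: [91, 96]}
    H: {CDR-H1: [26, 32], CDR-H2: [52, 56], CDR-H3: [96, 101]}

anchors:
  L: [4, 6, 23, 35, 62, 71, 82, 88, 98, 99]
  H: [4, 20, 22, 36, 47, 86, 92, 103, 104, 106]
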