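# abdb — antibody Fv extraction and classification from PDB files

Structural immunologists usually want neither a raw PDB entry nor a whole
crystal asymmetric unit: they want one antibody variable fragment (Fv) per
file, renumbered under a standard scheme, with its cognate antigen attached
and everything else stripped away. Getting there from deposited coordinates
is surprisingly intricate. A single entry may hold a dozen copies of the same
antibody, or three different antibodies glued to one antigen chain; a
light-chain dimer may appear as a single chain whose partner exists only in
the crystal symmetry; a staphylococcal protein A domain may grip the VH
framework and masquerade as an antigen; a hapten may sit in the binding site
or be covalently bolted to a chain; and two antibodies may bind *each other*
so that each is simultaneously antibody and antigen.

`abdb` is a pipeline that handles all of these cases. From legacy PDB files
and a list of entry ids it produces per-antibody Fv files annotated with
custom `REMARK 950` records, organised into a 3 × 4 × 3 taxonomy — antibody
form (complete, light-chain-only, heavy-chain-only) × complex class (free,
protein, non-protein, all) × numbering scheme (Kabat, Chothia, Martin) —
plus a non-redundant mirror of every dataset and lists of redundancy
clusters, free/complexed pairs and chain mappings.

## The rules at the core

* **Chain typing.** Every polymer chain is locally aligned (BLOSUM62) against
  frozen light- and heavy-chain variable-domain consensus sequences and
  scored as percent identity over the consensus length; both the SEQRES- and
  ATOM-derived sequences are scored and the better source kept. A chain
  provisionally typed light (heavy) is demoted to antigen when another chain
  scores strictly higher against the same consensus and its own score is
  below 80%.
* **Numbering.** Variable domains are numbered by profile alignment against
  per-scheme position tables (light 1–107; heavy 1–82, 82A–C, 83–113), with
  insertion codes placed at the scheme's anchors (Kabat: L27/H35;
  Chothia/Martin: L30/H31; all: H100 for CDR-H3). Constant domains and
  leader peptides are trimmed. Numbering fails cleanly — never wrongly —
  when fewer than half of the conserved framework anchors match.
* **Reassembly.** Light and heavy chains are paired by the maximal number of
  inter-chain contacts, a contact being two non-hydrogen atom centres within
  4 Å. Light dimers are paired when the Cα atoms of L36 and of L87 of the
  two chains each lie within 20 Å, reconstructing the partner from
  REMARK 350 BIOMT symmetry when the file holds only one chain.
* **Antigen assignment.** A polymer chain is antigen only if it makes more
  contacts with CDRs than with framework *and* at least 15 CDR contacts;
  proteins that touch the antibody without satisfying this are recorded as
  antibody-binding proteins and the antibody stays free. HETATM groups
  become antigens on a single CDR contact, unless CONECT records show them
  covalently bound. Entries holding only two sequence-distinct antibodies
  are screened for anti-idiotype binding, producing complementary sets in
  which each antibody also appears as the other's antigen.
* **Redundancy.** Two antibodies are redundant when every numbered position
  observed in both carries the same amino acid; missing positions are
  ignored. Clusters are the transitive closure of this relation; the
  representative is the longest structure at the best resolution.

## Worked example

Entries are processed one at a time with `abdb split`, or in bulk with
`abdb build --codes FILE --pdb-dir DIR --out DIR`. Using a generated entry
in which three sequence-distinct antibodies bind different parts of the same
antigen chain A:

```bash
$ abdb split scratch/demo/3ulx.pdb --out scratch/demo/split
scratch/demo/split/3ULX_1_chothia.pdb
scratch/demo/split/3ULX_1_kabat.pdb
scratch/demo/split/3ULX_1_martin.pdb
scratch/demo/split/3ULX_2_chothia.pdb
...
```

The entry is split into three sets (`3ULX_1` … `3ULX_3`), each holding one
antibody and its own copy of antigen chain A, under each numbering scheme.
Each file starts with the annotation block:

```text
REMARK 950 SCHEME KABAT
REMARK 950 METHOD X-RAY DIFFRACTION
REMARK 950 RESOLUTION 2.00
REMARK 950 RFACTOR 0.190
REMARK 950 RFREE 0.230
REMARK 950 CHAIN H D
REMARK 950 CHAIN L C
REMARK 950 CHAIN A A
REMARK 950 ABNAME SYNTHETIC FAB
```

i.e. this set's antibody was built from original chains C (light, now L) and
D (heavy, now H); antigen chains keep their original labels, lowered to
`l`/`h` only when they would collide with the antibody's. `abdb query
--index DIR --code 3ULX` then lists the three sets together with every set
whose antibody sequence is redundant with them.

Synthetic test entries covering every scenario above are produced by the
`abdb.fixtures` module (or `abdb fixtures` on the command line).

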