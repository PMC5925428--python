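# Methods

This note records the models, rules and numerical choices behind `abdb`, and
what the synthetic test corpus does and does not establish about behaviour
on real depositions.

## Scope and data model

The pipeline consumes legacy (fixed-column) PDB text. Only MODEL 1 of a
multi-model ensemble is kept, so each antibody contributes one coordinate
set. Alternate locations are reduced at parse time to the single
highest-occupancy conformer (ties: first in file), which makes residue and
contact counts independent of alt-loc bookkeeping. Blank chain identifiers
are mapped to the sentinel label `0` so that splitting can address every
chain. Waters are retained in the atom list but can never seed a hapten
group. CONECT records referencing unknown serials are dropped with a
warning. mmCIF, multi-character chain ids and full biological-assembly
generation beyond light-chain dimers are out of scope.

## Chain typing

Each polymer chain is scored against two frozen consensus sequences shipped
as package data: a 107-residue kappa-framework light consensus mapping 1:1
onto light positions 1–107, and a 116-residue VH3-like heavy consensus
mapping onto heavy positions 1–82, 82A–C, 83–113. The same files serve as
the numbering templates, so typing and numbering cannot drift apart. The
score is 100 × identities / consensus-length from a local BLOSUM62 alignment
(gap open −10, extend −0.5); a chain equal to a consensus scores exactly
100. Because the denominator is the consensus length, the 80% demotion
threshold has a concrete meaning: a chain must carry at least ~86 identical
light positions (or ~93 heavy) to be immune from demotion.

Decision rules, in order:

1. Nucleic-acid chains are always antigen.
2. Both the SEQRES- and ATOM-derived sequences are scored; the source with
   the higher best score wins (this tolerates unmodelled loops on the ATOM
   side and leader peptides on the SEQRES side).
3. Provisional type is whichever consensus scores higher (ties go light).
4. A provisional light (heavy) chain is demoted to antigen iff some other
   chain has a *strictly* higher light (heavy) score and its own score is
   < 80. Strictness means identical copies of one chain tie for the top
   score and none is demoted — identical sequences always get identical
   types (the Bence-Jones case).
5. Hybrid (scFv) detection: if the best-scoring segment clears 80%, that
   query span is masked with X and the remainder re-scored against both
   consensus sequences; a second segment ≥ 80% flags the chain as a hybrid
   and the entry is rejected rather than mis-numbered.
6. Entry form: light+heavy present → complete; one type only → light-only /
   heavy-only; no chain ≥ 80% → rejected (no variable domain, e.g. an Fc
   fragment).

## Numbering

Numbering is profile alignment against the template, not a port of any
existing numbering program; correctness is asserted through invariants
(unique ordered labels, exact inverse mapping to the input residues), not
byte-equivalence with external tools.

The query is globally aligned to the template with free end gaps, so leader
peptides and constant domains fall off the ends unaligned and are trimmed.
Within each hypervariable region the alignment's internal gap placement is
discarded and residues are relabelled deterministically around the scheme's
insertion anchor:

| region | Kabat | Chothia | Martin |
|---|---|---|---|
| CDR-L1 | 27 | 30 | 30 |
| CDR-L2 | 54 | 54 | 54 |
| CDR-L3 | 95 | 95 | 95 |
| CDR-H1 | 35 | 31 | 31 |
| CDR-H2 | 52 | 52 | 52 |
| CDR-H3 | 100 | 100 | 100 |
| heavy FR3 | (preceding) | (preceding) | 72 |

With n observed residues over m canonical positions: extra residues get
insertion letters A, B, … on the anchor; a shortfall removes the labels
immediately after the anchor. Framework regions trust the alignment, with
insertion letters attached to the preceding base position (skipping letters
already used by canonical columns such as heavy 82A–C). All three schemes
produce identical label sets for a sequence with no indels relative to
canon.

Failure is all-or-nothing: numbering returns a failure value when fewer than
half of ten conserved framework anchor positions per chain (e.g. the
invariant cysteines, L35/H36 tryptophans, H103 tryptophan) carry the
template residue, and any failed chain rejects the whole entry. Random
sequences fail this test essentially always; the test suite checks 20/20.

Structure renumbering aligns the ATOM-derived sequence to the numbered
sequence, so residues unobserved in the coordinates are numbered from SEQRES
while their atoms are simply absent, and observed residues that cannot be
mapped (interior extras, mismatches at non-X positions) reject the entry.

CDR membership for the contact rules uses the Kabat definition by default
(L24–34, L50–56, L89–97, H31–35, H50–65, H95–102), applied to whichever
numbering produced the label; the Chothia definition is available through
`PipelineParams.cdr_definition`.

## Geometry

All thresholds live in `PipelineParams`:

| parameter | default | meaning |
|---|---|---|
| `contact_cutoff` | 4.0 Å | inclusive atom-centre distance for a contact |
| `dimer_ca_cutoff` | 20.0 Å | max L36–L36 and L87–L87 Cα distances of a light dimer |
| `min_cdr_contacts` | 15 | minimum CDR contacts for a polymer antigen |
| `chain_score_threshold` | 80 % | consensus-identity demotion threshold |
| `het_min_cdr_contacts` | 1 | minimum CDR contacts for a hapten antigen |

The contact cutoff is applied as ≤ 4.0 Å uniformly. Hydrogens (and
deuteriums) are excluded from every contact computation — most X-ray
entries lack them, so counting them would make results
deposition-dependent — but are retained in output files when present.
Contacts are counted with a k-d tree; the test suite verifies exact
agreement with an all-pairs brute-force count on hundreds of random
configurations.

Light/heavy pairing is greedy on the contact matrix: repeatedly take the
unused pair with the most contacts, never forming zero-contact pairs, with
ties broken by chain-label order. Real multi-copy entries have
near-block-diagonal contact matrices, for which greedy and optimal matching
coincide; greedy reproduces the canonical anti-idiotype worked case
(128/20/10/117 → (A,B),(C,D)). With more than two light chains, dimer
candidates are taken closest-distance-sum first, each chain joining at most
one pair. Geometry (pairing, dimer rule, CDR contacts) is always evaluated
on Kabat-renumbered Fv atoms, since the dimer rule's L36/L87 are defined in
Kabat space.

## Antigen assignment

A candidate polymer chain is antigen iff it makes more CDR than framework
contacts *and* at least 15 CDR contacts. Chains that touch the antibody but
fail the rule are recorded as antibody-binding proteins (the protein-A
scenario) and leave the antibody free. For antigens spanning several chains,
chains individually passing are joined by any chains making ≥ 1 CDR contact
when their combined counts pass the rule (configurable to per-chain via
`multichain_combined`). DNA/RNA antigens follow the same rule but land in
the non-protein class.

HETATM groups are formed per residue and merged through CONECT bonds among
HETATMs, so an oligosaccharide is one group. A group is antigen on ≥ 1
CDR-involving contact — haptens are small, and demanding 15 contacts would
exclude genuine ones — unless a CONECT bond ties it to an antibody polymer
atom, in which case it is a covalent modification and the antibody stays
free.

Anti-idiotype screening runs only in entries whose polymer chains are all
antibody chains and which hold ≥ 2 antibodies. Identical-sequence copies
remain free; otherwise each antibody is offered as a two-chain antigen of
every sequence-distinct other, under the same CDR-dominance rule. Passing
pairs produce complementary protein-complex sets, each antibody once as
antibody and once as antigen; antigen-side antibody chains keep their
original labels (lowered on collision).

Light-dimer output labels the two light chains L and M (M rather than H, to
avoid implying a heavy chain); heavy-only antibodies are labelled H. An
antigen originally labelled L, H or M is lowered to l/h/m; a collision with
a pre-existing lowercase label rejects the entry rather than guessing.

## Redundancy

Redundancy is evaluated on the Martin-numbered, ATOM-observed sequences: two
antibodies of the same form are redundant when every position label present
in both (over all chains) carries the same amino acid; positions missing
from either are ignored, and no shared positions means not redundant. For a
light dimer the distinct light sequence is compared once. The relation is
not transitive (a structure with a disordered loop can bridge two variants
differing inside it), so clusters are its single-linkage closure, computed
per form × class and verified in the tests against an independent
union-find/graph-component oracle. Representatives: filter to maximal total
observed residue count, then minimal resolution value, entries without a
resolution (NMR, some EM) ranking after all resolved ones, final ties to the
smallest set id.

## Outputs

Datasets are laid out as `<form>/<class>/<scheme>/<set_id>.pdb` with
`NR_<form>/…` non-redundant mirrors — 36 dataset keys per redundancy level;
directories are only created for non-empty datasets. Twelve redundancy-
cluster lists (3 forms × 4 classes), three free/complexed lists and a
chain-mapping list are written as TSV, plus a flat `index.tsv` manifest that
backs `abdb query` (no database server). Output files replace the wwPDB
header with a fixed-grammar `REMARK 950 <KEY> <VALUE>` block (keys SCHEME,
METHOD, RESOLUTION, RFACTOR, RFREE, CHAIN new orig, ABNAME, ABSPECIES,
AGNAME, AGSPECIES); molecule names and species are read from COMPND/SOURCE
and omitted when absent. All iteration is sorted and no timestamps are
written, so identical input reproduces byte-identical output.

## The synthetic corpus, and what passing it shows

The fixture generator builds pseudo-physical scaffolds, not folds: backbone
plus Cβ pseudo-atoms along the chain axis, framework residues in a base
plane and CDR residues lifted 8 Å onto a paratope plane, partners placed
3.2 Å from their intended contact surface (inside the 4 Å rule), 3.8 Å
light/heavy separation, 100 Å between copies, 15 Å dimer translation.
Sequences are the shipped consensus domains, optionally CDR-mutated
per copy to make antibodies sequence-distinct. Scenario recipes cover: free
antibodies, protein/DNA antigens, a shared antigen binding three distinct
antibodies, 2- and 12-copy entries, anti-idiotype pairs, framework-only
binders, free and covalent haptens, explicit and BIOMT-reconstructed light
dimers, heavy-only domains, and entries that must be rejected (no variable
domain; fused VL–VH under one label).

Because the classification rules depend only on distances, labels and
sequences, this corpus exercises every decision branch exactly as real
coordinates would. What it does not establish: behaviour under real-world
coordinate noise (borderline 4 Å contacts, clashes), unusual germlines or
heavily engineered frameworks far from the consensus, real carbohydrate
connectivity, or agreement of the alignment-based numbering with any
specific external numbering program beyond the invariants stated above.
Archive-scale statistics are version-dependent and are not reproduced;
`scripts/acceptance.py` instead reports the per-scenario set counts and the
oracle agreement rates (contact counting, clustering, numbering round-trip,
rerun determinism) measured at generation time. Problem sizes there — a
15-entry corpus, 200 random contact configurations, ≤ 50-member clustering
instances, 100 numbered sequence variants per scheme — were chosen to cover
all branches while keeping the whole script in the seconds range.
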