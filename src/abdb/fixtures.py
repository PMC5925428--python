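"""Synthetic PDB entries with controlled antibody/antigen properties.

Real antibody coordinates cannot be assumed available, so every pipeline
stage is exercised against generated entries built on an idealized scaffold:
residues are laid out along the chain axis with backbone-plus-Cβ pseudo-atoms,
framework residues in a base plane and CDR residues lifted onto a "paratope
plane".  The classification rules depend only on distances, residue labels
and sequences, so this geometry is sufficient to drive every decision branch:
light/heavy interfaces produce contact-rich pairings, antigens placed over
the paratope plane touch only CDRs, framework binders placed under the base
plane touch only framework, BIOMT records regenerate light-dimer partners,
and CONECT records make haptens covalent.

Generation is deterministic per seed and every fixture parses via pdbio.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import pdbio
from .numbering import NumberedChain, cdr_membership, load_scheme_table, number_chain

SPACING = 1.5       # Å between consecutive residues along the chain axis
CDR_Z = 8.0         # Å lift of CDR residues onto the paratope plane
CONTACT_GAP = 3.2   # Å gap between binding partners (inside the 4 Å rule)
CHAIN_GAP_Y = 3.8   # Å light/heavy inter-chain separation

ANTIGEN_SEQ = "NAWVAWRNRAKGTDVQAWIRGARLNQELAKVT"
MUTABLE = "ADEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Recipe for one synthetic entry.

    ``antigen`` is one of none | protein | dna | hapten_free | hapten_covalent
    | framework_binder | anti_idiotype | shared_protein.  ``shared_protein``
    places a single antigen chain binding every antibody copy (the
    multi-antibody/one-antigen scenario); ``protein`` gives each copy its own
    antigen chain.  ``distinct`` mutates each copy's CDRs so the copies are
    sequence-distinct antibodies.
    """
    code: str = "1FIX"
    n_antibodies: int = 1
    form: str = "complete"  # complete | light_only | heavy_only
    antigen: str = "none"
    distinct: bool = False
    light_dimer_via_biomt: bool = False
    copy_separation: float = 100.0
    dimer_separation: float = 15.0
    resolution: float | None = 2.0
    r_factor: float | None = 0.19
    r_free: float | None = 0.23
    seed: int = 0
    scramble_labels: bool = False
    ab_name: str = "SYNTHETIC FAB"
    ag_name: str = "SYNTHETIC ANTIGEN"
    ab_species: str = "MUS MUSCULUS"
    ag_species: str = "HOMO SAPIENS"

    def __post_init__(self):
        if self.antigen == "anti_idiotype":
            self.n_antibodies = max(self.n_antibodies, 2)
            self.distinct = True


@dataclass
class _Chain:
    label: str
    atoms: list = field(default_factory=list)  # (name, res_name, res_seq, i_code, x, y, z, element, is_het)
    seq: str = ""
    is_het_only: bool = False


_BACKBONE = [("N", -0.6, 0.4, 0.0), ("CA", 0.0, 0.0, 0.0), ("C", 0.6, 0.4, 0.0),
             ("O", 0.9, 1.0, 0.3), ("CB", 0.0, -0.9, 0.6)]
_1TO3 = {v: k for k, v in pdbio._3TO1.items() if len(k) == 3 and k.isalpha()}
_1TO3.update({"A": "ALA", "C": "CYS", "G": "GLY", "M": "MET", "S": "SER",
              "T": "THR", "P": "PRO", "Y": "TYR", "K": "LYS", "Q": "GLN"})


def _residue_atoms(aa: str, cx: float, cy: float, cz: float, flip_z: bool) -> list:
    res_name = _1TO3.get(aa, "ALA")
    out = []
    for name, dx, dy, dz in _BACKBONE:
        if name == "CB" and res_name == "GLY":
            continue
        z = cz - dz if flip_z else cz + dz
        out.append((name, res_name, cx + dx, cy + dy, z, name[0]))
    return out


def make_fv_coordinates(seq_l: str | None, seq_h: str | None,
                        origin: tuple = (0.0, 0.0, 0.0),
                        flip_z: bool = False) -> dict:
    """Scaffold coordinates for an Fv (or single chain), keyed 'L'/'H'.

    Sequences must number successfully under the shipped Kabat table; CDR
    residues (Kabat definition) are lifted onto the paratope plane so the
    contact and dimer rules can be driven geometrically.  Returns
    {role: (_Chain-like atom tuples, NumberedChain)}.
    """
    table = load_scheme_table()
    x0, y0, z0 = origin
    out = {}
    for role, seq, y in (("L", seq_l, y0), ("H", seq_h, y0 + CHAIN_GAP_Y)):
        if seq is None:
            continue
        numbered = number_chain(seq, role, "kabat", table)
        if numbered is None:
            raise ValueError(f"{role} sequence is not numberable; cannot build scaffold")
        atoms = []
        for idx, r in enumerate(numbered.residues):
            in_cdr = cdr_membership(f"{r.number}{r.insertion}", role, "kabat",
                                    table) != "framework"
            lz = CDR_Z if in_cdr else 0.0
            cz = z0 - lz if flip_z else z0 + lz
            for name, res_name, ax, ay, az, el in _residue_atoms(
                    r.aa, x0 + SPACING * idx, y, cz, flip_z):
                atoms.append((name, res_name, idx + 1, "", ax, ay, az, el, False))
        out[role] = (atoms, numbered)
    return out


def _cdr_sites(atoms: list, numbered: NumberedChain, n: int) -> list:
    """(x, y, z) of the first n CDR Cα atoms of a scaffold chain."""
    table = load_scheme_table()
    cdr_res = {i + 1 for i, r in enumerate(numbered.residues)
               if cdr_membership(f"{r.number}{r.insertion}", numbered.role,
                                 "kabat", table) != "framework"}
    sites = [(x, y, z) for (name, _rn, rs, _ic, x, y, z, _el, _h) in atoms
             if name == "CA" and rs in cdr_res]
    return sites[:n]


def _framework_sites(atoms: list, numbered: NumberedChain, n: int) -> list:
    table = load_scheme_table()
    fw_res = {i + 1 for i, r in enumerate(numbered.residues)
              if cdr_membership(f"{r.number}{r.insertion}", numbered.role,
                                "kabat", table) == "framework"}
    sites = [(x, y, z) for (name, _rn, rs, _ic, x, y, z, _el, _h) in atoms
             if name == "CA" and rs in fw_res]
    # pick sites from the middle of the framework, away from chain termini
    start = max(0, len(sites) // 3)
    return sites[start:start + n]


def _protein_chain_at(sites: list, seq: str, flip: bool = False) -> list:
    atoms = []
    for i, (sx, sy, sz) in enumerate(sites):
        aa = seq[i % len(seq)]
        dz = -CONTACT_GAP if flip else CONTACT_GAP
        for name, res_name, ax, ay, az, el in _residue_atoms(aa, sx, sy, sz + dz, flip):
            atoms.append((name, res_name, i + 1, "", ax, ay, az, el, False))
    return atoms


def _dna_chain_at(sites: list) -> list:
    names = ["DA", "DT", "DG", "DC"]
    atoms = []
    for i, (sx, sy, sz) in enumerate(sites):
        rn = names[i % 4]
        for name, dx in (("P", -0.5), ("O5'", 0.0), ("C1'", 0.5)):
            atoms.append((name, rn, i + 1, "", sx + dx, sy, sz + CONTACT_GAP,
                          name[0], False))
    return atoms


def _mutated(seq: str, numbered: NumberedChain, rng: random.Random, n_mut: int) -> str:
    """Substitute n_mut CDR residues (never anchors) so copies differ."""
    table = load_scheme_table()
    cdr_idx = [r.seq_index for r in numbered.residues
               if cdr_membership(f"{r.number}{r.insertion}", numbered.role,
                                 "kabat", table) != "framework"]
    chosen = rng.sample(cdr_idx, min(n_mut, len(cdr_idx)))
    out = list(seq)
    for i in chosen:
        choices = [c for c in MUTABLE if c != out[i]]
        out[i] = rng.choice(choices)
    return "".join(out)


_PAIR_LABELS = [("L", "H"), ("K", "M"), ("C", "D"), ("E", "F"), ("I", "J"),
                ("N", "O"), ("P", "Q"), ("R", "S"), ("T", "U"), ("V", "W"),
                ("X", "Y"), ("Z", "1")]
_ANTIGEN_LABELS = ["A", "B", "G", "2", "3", "4", "5", "6", "7", "8", "9", "a"]


def consensus_sequences() -> tuple[str, str]:
    table = load_scheme_table()
    return table.template["L"], table.template["H"]


def make_entry(spec: FixtureSpec) -> str:
    """Full legacy-PDB text for one synthetic entry."""
    rng = random.Random(spec.seed)
    seq_l0, seq_h0 = consensus_sequences()
    table = load_scheme_table()
    num_l0 = number_chain(seq_l0, "L", "kabat", table)
    num_h0 = number_chain(seq_h0, "H", "kabat", table)

    chains: list = []
    conect_pairs: list = []
    biomt = None

    if spec.form == "light_only" and spec.light_dimer_via_biomt:
        n_copies = 1
    else:
        n_copies = spec.n_antibodies

    copies = []  # (labels dict role->label, scaffold dict)
    for k in range(n_copies):
        if spec.distinct and k > 0:
            seq_l = _mutated(seq_l0, num_l0, rng, 4)
            seq_h = _mutated(seq_h0, num_h0, rng, 4)
        else:
            seq_l, seq_h = seq_l0, seq_h0
        if spec.antigen == "anti_idiotype" and k == 1:
            origin, flip = (0.0, 0.0, 2 * CDR_Z + CONTACT_GAP), True
        else:
            origin, flip = (0.0, spec.copy_separation * k, 0.0), False
        if spec.form == "complete":
            scaffold = make_fv_coordinates(seq_l, seq_h, origin, flip)
            labels = {"L": _PAIR_LABELS[k][0], "H": _PAIR_LABELS[k][1]}
        elif spec.form == "light_only":
            scaffold = make_fv_coordinates(seq_l, None, origin, flip)
            labels = {"L": _PAIR_LABELS[k][0]}
        else:
            scaffold = make_fv_coordinates(None, seq_h, origin, flip)
            labels = {"H": _PAIR_LABELS[k][1]}
        copies.append((labels, scaffold))
        for role, label in labels.items():
            atoms, numbered = scaffold[role]
            chains.append(_Chain(label=label, atoms=list(atoms),
                                 seq="".join(r.aa for r in numbered.residues)))

    if spec.form == "light_only" and not spec.light_dimer_via_biomt \
            and spec.n_antibodies >= 1:
        # explicit second light chain of the dimer, translated along y
        labels, scaffold = copies[0]
        atoms, numbered = scaffold["L"]
        moved = [(n, rn, rs, ic, x, y + spec.dimer_separation, z, el, h)
                 for (n, rn, rs, ic, x, y, z, el, h) in atoms]
        chains.append(_Chain(label="B", atoms=moved,
                             seq="".join(r.aa for r in numbered.residues)))
    if spec.form == "light_only" and spec.light_dimer_via_biomt:
        d = spec.dimer_separation
        biomt = ((1.0, -1.0, -1.0), (0.0, d, 0.0))  # C2: (x, d-y, -z)

    ag_labels = []
    if spec.antigen in ("protein", "dna"):
        for k, (labels, scaffold) in enumerate(copies):
            role = "L" if "L" in labels else "H"
            atoms, numbered = scaffold[role]
            sites = _cdr_sites(atoms, numbered, 8)
            if "H" in scaffold and "L" in scaffold:
                h_atoms, h_num = scaffold["H"]
                sites += _cdr_sites(h_atoms, h_num, 4)
            lbl = _ANTIGEN_LABELS[k]
            ag_labels.append(lbl)
            if spec.antigen == "dna":
                chains.append(_Chain(label=lbl, atoms=_dna_chain_at(sites)))
            else:
                ch = _Chain(label=lbl, atoms=_protein_chain_at(sites, ANTIGEN_SEQ))
                ch.seq = "".join(ANTIGEN_SEQ[i % len(ANTIGEN_SEQ)]
                                 for i in range(len(sites)))
                chains.append(ch)
    elif spec.antigen == "shared_protein":
        sites = []
        for labels, scaffold in copies:
            role = "L" if "L" in scaffold else "H"
            atoms, numbered = scaffold[role]
            sites += _cdr_sites(atoms, numbered, 8)
        ch = _Chain(label="A", atoms=_protein_chain_at(sites, ANTIGEN_SEQ))
        ch.seq = "".join(ANTIGEN_SEQ[i % len(ANTIGEN_SEQ)] for i in range(len(sites)))
        ag_labels.append("A")
        chains.append(ch)
    elif spec.antigen == "framework_binder":
        labels, scaffold = copies[0]
        role = "L" if "L" in scaffold else "H"
        atoms, numbered = scaffold[role]
        sites = _framework_sites(atoms, numbered, 10)
        ch = _Chain(label="A", atoms=_protein_chain_at(sites, ANTIGEN_SEQ, flip=True))
        ch.seq = "".join(ANTIGEN_SEQ[i % len(ANTIGEN_SEQ)] for i in range(len(sites)))
        ag_labels.append("A")
        chains.append(ch)
    elif spec.antigen in ("hapten_free", "hapten_covalent"):
        labels, scaffold = copies[0]
        role = "H" if "H" in scaffold else "L"
        atoms, numbered = scaffold[role]
        sx, sy, sz = _cdr_sites(atoms, numbered, 1)[0]
        hap = _Chain(label=labels[role], is_het_only=True)
        for i, (dx, dy) in enumerate([(0, 0), (1.2, 0), (0, 1.2), (-1.2, 0), (0, -1.2)]):
            hap.atoms.append((f"C{i+1}", "HAP", 500, "", sx + dx, sy + dy,
                              sz + CONTACT_GAP, "C", True))
        chains.append(hap)

    # --- render ---
    lines = []
    code = spec.code.upper()
    lines.append("HEADER    IMMUNE SYSTEM".ljust(50) + "01-JAN-18".ljust(12) + code)
    lines.append("EXPDTA    X-RAY DIFFRACTION")
    if spec.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {spec.resolution:.2f} ANGSTROMS.")
    if spec.r_factor is not None:
        lines.append(f"REMARK   3   R VALUE            (WORKING SET) : {spec.r_factor:.3f}")
    if spec.r_free is not None:
        lines.append(f"REMARK   3   FREE R VALUE                     : {spec.r_free:.3f}")
    ab_chain_labels = sorted({c.label for c in chains
                              if not c.is_het_only and c.label not in ag_labels})
    mol_id = 1
    for group, name, species in ((ab_chain_labels, spec.ab_name, spec.ab_species),
                                 (ag_labels, spec.ag_name, spec.ag_species)):
        if not group:
            continue
        lines.append(f"COMPND    MOL_ID: {mol_id};")
        lines.append(f"COMPND   2 MOLECULE: {name};")
        lines.append(f"COMPND   3 CHAIN: {', '.join(group)};")
        lines.append(f"SOURCE    MOL_ID: {mol_id};")
        lines.append(f"SOURCE   2 ORGANISM_SCIENTIFIC: {species};")
        mol_id += 1
    lines.append("REMARK 350 BIOMOLECULE: 1")
    lines.append("REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000")
    lines.append("REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000")
    lines.append("REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000")
    if biomt is not None:
        diag, trans = biomt
        for row in range(3):
            vals = [0.0, 0.0, 0.0]
            vals[row] = diag[row]
            lines.append(f"REMARK 350   BIOMT{row+1}   2 "
                         f"{vals[0]:9.6f} {vals[1]:9.6f} {vals[2]:9.6f} "
                         f"{trans[row]:14.5f}")

    order = list(range(len(chains)))
    if spec.scramble_labels:
        rng.shuffle(order)
    for ci in order:
        c = chains[ci]
        if not c.seq:
            continue
        names = [_1TO3.get(aa, "ALA") for aa in c.seq]
        for snum, start in enumerate(range(0, len(names), 13), start=1):
            chunk = " ".join(f"{n:>3s}" for n in names[start:start + 13])
            lines.append(f"SEQRES{snum:4d} {c.label}{len(names):5d}  {chunk}")
    serial = 0
    hap_serials: list = []
    first_cdr_serial = None
    for ci in order:
        c = chains[ci]
        for (name, res_name, res_seq, i_code, x, y, z, el, is_het) in c.atoms:
            serial += 1
            rec = pdbio.AtomRecord(serial=serial, name=name, alt_loc="",
                                   res_name=res_name, chain_label=c.label,
                                   res_seq=res_seq, i_code=i_code, x=x, y=y, z=z,
                                   occupancy=1.0, b_factor=20.0, element=el,
                                   is_het=is_het)
            lines.append(pdbio.format_atom_line(rec))
            if is_het and res_name == "HAP":
                hap_serials.append(serial)
            if first_cdr_serial is None and not is_het and name == "CA" and z >= CDR_Z:
                first_cdr_serial = serial
        lines.append("TER")
    # intra-hapten connectivity; covalent variant also bonds to an antibody atom
    for i in range(1, len(hap_serials)):
        conect_pairs.append((hap_serials[0], hap_serials[i]))
    if spec.antigen == "hapten_covalent" and hap_serials and first_cdr_serial:
        conect_pairs.append((hap_serials[0], first_cdr_serial))
    for s1, s2 in conect_pairs:
        lines.append(f"CONECT{s1:5d}{s2:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_nonantibody_entry(code: str = "1FCX", length: int = 200, seed: int = 0) -> str:
    """An entry with no variable domain (rejected as Fc-only downstream)."""
    rng = random.Random(seed)
    seq = "".join(rng.choice(MUTABLE) for _ in range(length))
    lines = ["HEADER    IMMUNE SYSTEM".ljust(50) + "01-JAN-18".ljust(12) + code.upper(),
             "EXPDTA    X-RAY DIFFRACTION",
             "REMARK   2 RESOLUTION.    2.50 ANGSTROMS."]
    serial = 0
    for i, aa in enumerate(seq):
        for name, res_name, x, y, z, el in _residue_atoms(aa, SPACING * i, 0.0, 0.0, False):
            serial += 1
            rec = pdbio.AtomRecord(serial, name, "", res_name, "A", i + 1, "",
                                   x, y, z, 1.0, 20.0, el, False)
            lines.append(pdbio.format_atom_line(rec))
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


def make_scfv_entry(code: str = "1SCF", seed: int = 0) -> str:
    """A single-chain entry fusing VL and VH under one label (rejected as hybrid)."""
    seq_l, seq_h = consensus_sequences()
    seq = seq_l + "GGGGSGGGGS" + seq_h
    lines = ["HEADER    IMMUNE SYSTEM".ljust(50) + "01-JAN-18".ljust(12) + code.upper(),
             "EXPDTA    X-RAY DIFFRACTION",
             "REMARK   2 RESOLUTION.    2.80 ANGSTROMS."]
    serial = 0
    for i, aa in enumerate(seq):
        for name, res_name, x, y, z, el in _residue_atoms(aa, SPACING * i, 0.0, 0.0, False):
            serial += 1
            rec = pdbio.AtomRecord(serial, name, "", res_name, "A", i + 1, "",
                                   x, y, z, 1.0, 20.0, el, False)
            lines.append(pdbio.format_atom_line(rec))
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"
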