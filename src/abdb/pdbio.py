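"""Reading and writing legacy (fixed-column) PDB files.

This module owns the on-disk representation used by the pipeline: it parses
ATOM/HETATM/SEQRES/CONECT/REMARK 2/REMARK 3/REMARK 350 records into a
:class:`StructureModel` and writes processed antibody/antigen sets back out as
PDB text whose bulk header is replaced by custom ``REMARK 950`` annotations.

Only the first MODEL of a multi-model (NMR) entry is retained.  Alternate
locations are reduced to the highest-occupancy conformer at parse time, so
residue and contact counts downstream do not depend on alt-loc bookkeeping.
A blank chain identifier is mapped to the sentinel label ``"0"`` so that every
chain is addressable when an entry is split.
"""
from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

# one-letter codes, including the common modified residues seen in PDB entries
_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O", "HYP": "P", "SEP": "S", "TPO": "T",
    "PTR": "Y", "CSO": "C", "MLY": "K", "M3L": "K", "KCX": "K", "PCA": "Q",
}

NUCLEIC_RES = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DI"}
WATER_RES = {"HOH", "DOD", "WAT"}

CHAIN_LABEL_POOL = string.ascii_uppercase + string.digits + string.ascii_lowercase


class EmptyStructureError(ValueError):
    """Raised when a PDB text contains no coordinate records."""


def three_to_one(res_name: str) -> str:
    return _3TO1.get(res_name.strip().upper(), "X")


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    alt_loc: str
    res_name: str
    chain_label: str
    res_seq: int
    i_code: str
    x: float
    y: float
    z: float
    occupancy: float
    b_factor: float
    element: str
    is_het: bool

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def residue_id(self) -> tuple:
        return (self.chain_label, self.res_seq, self.i_code, self.res_name)

    @property
    def is_hydrogen(self) -> bool:
        el = self.element.strip().upper()
        if el:
            return el in ("H", "D")
        # fall back to the atom-name convention when the element column is blank
        name = self.name.strip()
        return bool(name) and name.lstrip("0123456789")[:1].upper() in ("H", "D")


@dataclass(frozen=True)
class TransformMatrix:
    rotation: tuple  # 3x3, row-major nested tuples
    translation: tuple  # 3-vector
    biomolecule_id: int

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.array(self.rotation, dtype=float), np.array(self.translation, dtype=float)

    @property
    def is_identity(self) -> bool:
        r, t = self.as_arrays()
        return np.allclose(r, np.eye(3), atol=1e-6) and np.allclose(t, 0.0, atol=1e-6)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        r, t = self.as_arrays()
        return xyz @ r.T + t


@dataclass
class HeaderMeta:
    pdb_code: str = ""
    method: str = ""
    resolution: float | None = None
    r_factor: float | None = None
    r_free: float | None = None
    # per-original-chain annotations from COMPND / SOURCE
    molecule_names: dict = field(default_factory=dict)
    species: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")


@dataclass
class StructureModel:
    header: HeaderMeta
    atoms: list  # list[AtomRecord], file order, model 1 only
    seqres_residues: dict = field(default_factory=dict)  # chain -> [3-letter names]
    conect: set = field(default_factory=set)  # {(serial_lo, serial_hi)}
    transforms: list = field(default_factory=list)  # list[TransformMatrix]
    symmetry_copies: dict = field(default_factory=dict)  # new label -> (source label, TransformMatrix)

    @property
    def seqres(self) -> dict:
        """SEQRES one-letter sequences for protein chains."""
        out = {}
        for ch, names in self.seqres_residues.items():
            if all(n in NUCLEIC_RES for n in names):
                continue
            out[ch] = "".join(three_to_one(n) for n in names)
        return out

    def polymer_chains(self) -> list:
        """Chain labels with polymer (ATOM) records or SEQRES entries, file order."""
        seen: list = []
        for a in self.atoms:
            if not a.is_het and a.chain_label not in seen:
                seen.append(a.chain_label)
        for ch in self.seqres_residues:
            if ch not in seen:
                seen.append(ch)
        return seen

    def chain_atoms(self, chain: str, het: bool | None = False) -> list:
        """Atoms of one chain; het=False polymer only, True HETATM only, None all."""
        return [a for a in self.atoms
                if a.chain_label == chain and (het is None or a.is_het == het)]

    def residues_of_chain(self, chain: str) -> list:
        """Ordered unique polymer residues (chain, res_seq, i_code, res_name) of a chain."""
        out, seen = [], set()
        for a in self.chain_atoms(chain):
            if a.residue_id not in seen:
                seen.add(a.residue_id)
                out.append(a.residue_id)
        return out

    def is_nucleic(self, chain: str) -> bool:
        names = {a.res_name.strip() for a in self.chain_atoms(chain)}
        if not names:
            names = set(self.seqres_residues.get(chain, ()))
        return bool(names) and names <= NUCLEIC_RES


def _parse_atom_line(line: str, is_het: bool) -> AtomRecord:
    chain = line[21] if len(line) > 21 else " "
    return AtomRecord(
        serial=int(line[6:11]),
        name=line[12:16].strip(),
        alt_loc=line[16].strip(),
        res_name=line[17:20].strip(),
        chain_label="0" if chain == " " else chain,
        res_seq=int(line[22:26]),
        i_code=line[26].strip() if len(line) > 26 else "",
        x=float(line[30:38]),
        y=float(line[38:46]),
        z=float(line[46:54]),
        occupancy=float(line[54:60]) if line[54:60].strip() else 1.0,
        b_factor=float(line[60:66]) if line[60:66].strip() else 0.0,
        element=line[76:78].strip() if len(line) > 76 else "",
        is_het=is_het,
    )


def _reduce_alt_locs(atoms: list) -> list:
    """Keep the highest-occupancy conformer per (residue, atom name); ties keep the first."""
    best: dict = {}
    order: list = []
    for idx, a in enumerate(atoms):
        key = (a.chain_label, a.res_seq, a.i_code, a.res_name, a.name)
        if key not in best:
            best[key] = (idx, a)
            order.append(key)
        elif a.occupancy > best[key][1].occupancy:
            best[key] = (best[key][0], a)  # keep original position in file order
    reduced = [best[k][1] for k in sorted(order, key=lambda k: best[k][0])]
    return [replace(a, alt_loc="") for a in reduced]


def _specification_list(records: list) -> dict:
    """Parse COMPND/SOURCE continuation text into {mol_id: {token: value}}."""
    out: dict = {}
    mol_id = None
    for chunk in " ".join(records).split(";"):
        if ":" not in chunk:
            continue
        key, _, val = chunk.partition(":")
        key = key.strip().upper()
        val = val.strip().rstrip(".")
        if key == "MOL_ID":
            try:
                mol_id = int(val)
            except ValueError:
                mol_id = None
            out.setdefault(mol_id, {})
        elif mol_id is not None:
            out[mol_id][key] = val
    return out


def _fill_entity_annotations(compnd_lines: list, source_lines: list,
                             header: "HeaderMeta") -> None:
    """Chains are listed in COMPND; SOURCE entities join on MOL_ID."""
    compnd = _specification_list(compnd_lines)
    source = _specification_list(source_lines)
    for mol_id, tokens in compnd.items():
        chains = [c.strip() for c in tokens.get("CHAIN", "").split(",") if c.strip()]
        for ch in chains:
            if tokens.get("MOLECULE"):
                header.molecule_names.setdefault(ch, tokens["MOLECULE"])
            organism = source.get(mol_id, {}).get("ORGANISM_SCIENTIFIC", "")
            if organism:
                header.species.setdefault(ch, organism)


def parse_pdb(text: str) -> StructureModel:
    """Parse legacy PDB text into a :class:`StructureModel`.

    Raises :class:`EmptyStructureError` when no ATOM/HETATM record is present.
    Malformed fixed-column coordinate lines are skipped with a logged warning.
    """
    atoms: list = []
    seqres_residues: dict = {}
    conect_raw: list = []
    transforms: list = []
    header = HeaderMeta()
    compnd_lines: list = []
    source_lines: list = []

    model_no = 0
    in_first_model = True
    biomol_id = 1
    biomt_rows: dict = {}  # transform index -> [row1, row2, row3]

    for line in text.splitlines():
        rec = line[:6]
        if rec == "MODEL ":
            model_no += 1
            in_first_model = model_no <= 1
        elif rec == "ENDMDL":
            in_first_model = False if model_no >= 1 else True
        elif rec in ("ATOM  ", "HETATM"):
            if not in_first_model:
                continue
            try:
                atoms.append(_parse_atom_line(line, rec == "HETATM"))
            except (ValueError, IndexError):
                log.warning("skipping malformed coordinate line: %r", line)
        elif rec == "SEQRES":
            chain = line[11] if len(line) > 11 else " "
            chain = "0" if chain == " " else chain
            names = line[19:].split()
            seqres_residues.setdefault(chain, []).extend(names)
        elif rec == "CONECT":
            serials = []
            for start in (6, 11, 16, 21, 26):
                fld = line[start:start + 5].strip()
                if fld:
                    try:
                        serials.append(int(fld))
                    except ValueError:
                        pass
            for other in serials[1:]:
                conect_raw.append((serials[0], other))
        elif rec == "HEADER":
            header.pdb_code = line[62:66].strip()
        elif rec == "EXPDTA":
            header.method = line[10:].strip()
        elif rec == "COMPND":
            compnd_lines.append(line[10:].rstrip())
        elif rec == "SOURCE":
            source_lines.append(line[10:].rstrip())
        elif rec == "REMARK":
            try:
                remark_no = int(line[7:10])
            except ValueError:
                continue
            if remark_no == 2 and "RESOLUTION." in line:
                toks = line.split("RESOLUTION.", 1)[1].split()
                if toks and toks[0].replace(".", "", 1).isdigit():
                    header.resolution = float(toks[0])
            elif remark_no == 3:
                body = line[10:]
                if "R VALUE" in body and "WORKING SET" in body and ":" in body:
                    val = body.rsplit(":", 1)[1].strip()
                    try:
                        header.r_factor = float(val)
                    except ValueError:
                        pass
                elif "FREE R VALUE" in body and "TEST" not in body and "ERROR" not in body \
                        and "SET" not in body and ":" in body:
                    val = body.rsplit(":", 1)[1].strip()
                    try:
                        header.r_free = float(val)
                    except ValueError:
                        pass
            elif remark_no == 350:
                body = line[10:]
                if "BIOMOLECULE:" in body:
                    # flush any pending matrices belonging to the previous biomolecule
                    biomol_id = int(body.split("BIOMOLECULE:")[1].split()[0])
                elif body.strip().startswith("BIOMT"):
                    toks = body.split()
                    row = int(toks[0][-1])  # BIOMT1/2/3
                    tidx = int(toks[1])
                    vals = [float(v) for v in toks[2:6]]
                    biomt_rows.setdefault((biomol_id, tidx), {})[row] = vals
    # assemble BIOMT matrices
    for (bid, _tidx), rows in sorted(biomt_rows.items()):
        if set(rows) != {1, 2, 3}:
            log.warning("incomplete BIOMT matrix in biomolecule %d; skipped", bid)
            continue
        rot = tuple(tuple(rows[r][:3]) for r in (1, 2, 3))
        trans = tuple(rows[r][3] for r in (1, 2, 3))
        transforms.append(TransformMatrix(rot, trans, bid))

    if not atoms:
        raise EmptyStructureError("empty structure: no ATOM/HETATM records")

    atoms = _reduce_alt_locs(atoms)
    serials = {a.serial for a in atoms}
    conect = set()
    for a, b in conect_raw:
        if a in serials and b in serials:
            if a != b:
                conect.add((min(a, b), max(a, b)))
        else:
            log.warning("CONECT references unknown serial (%d, %d); dropped", a, b)

    _fill_entity_annotations(compnd_lines, source_lines, header)
    return StructureModel(header=header, atoms=atoms, seqres_residues=seqres_residues,
                          conect=conect, transforms=transforms)


def sequence_from_atoms(model: StructureModel, chain: str) -> str:
    """One-letter sequence of a chain's polymer residues, in file order.

    Residues missing from the coordinates (unmodelled loops) simply do not
    appear; no gap characters are introduced.  Unknown residue names map to X.
    """
    residues = model.residues_of_chain(chain)
    if not residues:
        raise KeyError(f"chain {chain!r} has no polymer residues")
    return "".join(three_to_one(r[3]) for r in residues)


def expand_symmetry(model: StructureModel, chains: list | None = None) -> StructureModel:
    """Append BIOMT-transformed copies of the requested chains under fresh labels.

    The identity copy is preserved bit-for-bit.  With no non-identity
    transform the input model is returned unchanged.
    """
    non_identity = [t for t in model.transforms if not t.is_identity]
    if not non_identity:
        return model
    if chains is None:
        chains = model.polymer_chains()
    used = {a.chain_label for a in model.atoms}
    pool = iter(c for c in CHAIN_LABEL_POOL if c not in used)
    new_atoms = list(model.atoms)
    copies = dict(model.symmetry_copies)
    serial = max(a.serial for a in model.atoms)
    for t in non_identity:
        for ch in chains:
            src = [a for a in model.atoms if a.chain_label == ch]
            if not src:
                continue
            try:
                label = next(pool)
            except StopIteration:
                raise ValueError("no free chain labels for symmetry expansion")
            for a in src:
                serial += 1
                nx, ny, nz = t.apply(a.coord)
                new_atoms.append(replace(a, serial=serial, chain_label=label,
                                         x=float(nx), y=float(ny), z=float(nz)))
            copies[label] = (ch, t)
    return StructureModel(header=model.header, atoms=new_atoms,
                          seqres_residues=dict(model.seqres_residues),
                          conect=set(model.conect), transforms=list(model.transforms),
                          symmetry_copies=copies)


def format_atom_line(a: AtomRecord, serial: int | None = None) -> str:
    name = a.name
    if len(name) < 4:
        # standard convention: 1-3 character names start in column 14
        name = " " + name
    rec = "HETATM" if a.is_het else "ATOM  "
    return (f"{rec}{serial if serial is not None else a.serial:5d} "
            f"{name:<4s}{a.alt_loc or ' ':1s}{a.res_name:>3s} "
            f"{a.chain_label:1s}{a.res_seq:4d}{a.i_code or ' ':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
            f"          {a.element:>2s}")


def write_fv_file(abag_set, scheme: str, meta: HeaderMeta, mapping: dict) -> str:
    """Render one antibody/antigen set as annotated PDB text.

    ``mapping`` maps each output chain label to its original label in the
    source entry.  The bulk wwPDB header is replaced by a REMARK 950 block
    carrying the numbering scheme, the experimental metadata, the chain
    mapping and the molecule name/species annotations.  Output is canonical:
    identical input always produces identical bytes.
    """
    ab_atoms = list(abag_set.antibody_atoms)
    ag_atoms = list(getattr(abag_set, "antigen_atoms", []) or [])
    if not ab_atoms:
        raise ValueError("antibody chains are not numbered; nothing to write")
    ab_labels = []
    for a in ab_atoms:
        if a.chain_label not in ab_labels:
            ab_labels.append(a.chain_label)
    for lbl in ab_labels:
        if lbl not in mapping:
            raise ValueError(f"antibody chain {lbl!r} missing from the chain mapping")

    lines = [f"REMARK 950 SCHEME {scheme.upper()}"]
    if meta.method:
        lines.append(f"REMARK 950 METHOD {meta.method}")
    if meta.resolution is not None:
        lines.append(f"REMARK 950 RESOLUTION {meta.resolution:.2f}")
    if meta.r_factor is not None:
        lines.append(f"REMARK 950 RFACTOR {meta.r_factor:.3f}")
    if meta.r_free is not None:
        lines.append(f"REMARK 950 RFREE {meta.r_free:.3f}")
    ag_labels = []
    for a in ag_atoms:
        if a.chain_label not in ag_labels:
            ag_labels.append(a.chain_label)
    for lbl in ab_labels + ag_labels:
        lines.append(f"REMARK 950 CHAIN {lbl} {mapping.get(lbl, lbl)}")

    def first_annot(labels, table):
        for lbl in labels:
            orig = mapping.get(lbl, lbl)
            if table.get(orig):
                return table[orig]
        return ""

    ab_name = first_annot(ab_labels, meta.molecule_names)
    ab_species = first_annot(ab_labels, meta.species)
    if ab_name:
        lines.append(f"REMARK 950 ABNAME {ab_name}")
    if ab_species:
        lines.append(f"REMARK 950 ABSPECIES {ab_species}")
    if ag_atoms:
        ag_name = first_annot(ag_labels, meta.molecule_names)
        ag_species = first_annot(ag_labels, meta.species)
        if ag_name:
            lines.append(f"REMARK 950 AGNAME {ag_name}")
        if ag_species:
            lines.append(f"REMARK 950 AGSPECIES {ag_species}")

    serial = 0
    prev_chain = None
    for a in ab_atoms + ag_atoms:
        if prev_chain is not None and a.chain_label != prev_chain:
            lines.append("TER")
        serial += 1
        lines.append(format_atom_line(a, serial))
        prev_chain = a.chain_label
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
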