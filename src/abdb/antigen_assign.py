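"""Deciding what, if anything, each antibody binds.

A candidate polymer chain is an antigen only when it interacts predominantly
with the antibody's CDRs: it must make more contacts with CDR residues than
with framework residues and at least 15 CDR contacts in total.  Proteins that
touch the antibody but fail this rule — such as staphylococcal protein A,
which grips conserved framework residues of VH3 domains — are recorded as
antibody-binding proteins and the antibody stays free.

HETATM groups (haptens, lipids, carbohydrates) become antigens when at least
one of their atoms contacts a CDR residue and no CONECT record covalently
ties the group to the antibody.  Entries holding two sequence-distinct
antibodies and nothing else are screened for anti-idiotype binding: each
antibody is tried in turn as a two-chain antigen of the other, and passing
pairs yield complementary protein-complex sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import pdbio
from .assembly import AbAgSet, _heavy_coords
from .numbering import SchemeTable, cdr_membership, load_scheme_table
from .params import PipelineParams


@dataclass
class CdrContactProfile:
    partner: str
    cdr_contacts: int
    framework_contacts: int

    def __post_init__(self):
        if self.cdr_contacts < 0 or self.framework_contacts < 0:
            raise ValueError("contact counts must be non-negative")

    @property
    def total(self) -> int:
        return self.cdr_contacts + self.framework_contacts


@dataclass
class HetGroup:
    group_id: tuple  # (res_name, chain_label, res_seq, i_code) of the lead residue
    atoms: list
    covalent_to_antibody: bool = False

    def __post_init__(self):
        if any(a.res_name in pdbio.WATER_RES for a in self.atoms):
            raise ValueError("waters cannot form a hapten group")


def cdr_contact_profile(ab_set: AbAgSet, partner_atoms: list, partner_id: str,
                        params: PipelineParams | None = None,
                        table: SchemeTable | None = None) -> CdrContactProfile:
    """Count the partner's contacts against the antibody's CDR vs framework atoms."""
    params = params or PipelineParams()
    table = table or load_scheme_table()
    roles = ab_set.roles
    ab_atoms = [a for a in ab_set.antibody_atoms if not a.is_hydrogen]
    partner = _heavy_coords(partner_atoms)
    if len(ab_atoms) == 0 or len(partner) == 0:
        return CdrContactProfile(partner_id, 0, 0)
    tree = cKDTree(partner)
    counts = tree.query_ball_point(np.array([(a.x, a.y, a.z) for a in ab_atoms]),
                                   params.contact_cutoff, return_length=True)
    cdr = fw = 0
    for a, n in zip(ab_atoms, counts):
        if n == 0:
            continue
        label = f"{a.res_seq}{a.i_code}"
        region = cdr_membership(label, roles[a.chain_label], "kabat", table,
                                definition=params.cdr_definition)
        if region == "framework":
            fw += int(n)
        else:
            cdr += int(n)
    return CdrContactProfile(partner_id, cdr, fw)


def classify_polymer_antigen(ab_set: AbAgSet, chain: str, model: pdbio.StructureModel,
                             params: PipelineParams | None = None,
                             table: SchemeTable | None = None,
                             partner_atoms: list | None = None) -> str:
    """antigen | antibody_binding_protein | unrelated for one candidate chain."""
    params = params or PipelineParams()
    atoms = partner_atoms if partner_atoms is not None else model.chain_atoms(chain)
    prof = cdr_contact_profile(ab_set, atoms, chain, params, table)
    if prof.total == 0:
        return "unrelated"
    if prof.cdr_contacts > prof.framework_contacts and \
            prof.cdr_contacts >= params.min_cdr_contacts:
        return "antigen"
    return "antibody_binding_protein"


def collect_het_groups(model: pdbio.StructureModel, antibody_serials: set) -> list:
    """Group non-water HETATMs into candidate hapten/glycan groups.

    HET residues joined to each other by CONECT records are merged into one
    group; a group is covalent to the antibody when any CONECT pair links one
    of its atoms to an antibody polymer atom.
    """
    het_atoms = [a for a in model.atoms if a.is_het and a.res_name not in pdbio.WATER_RES]
    if not het_atoms:
        return []
    by_serial = {a.serial: a for a in het_atoms}
    parent = {a.serial: a.serial for a in het_atoms}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # same HET residue -> same group
    by_residue: dict = {}
    for a in het_atoms:
        by_residue.setdefault(a.residue_id, []).append(a)
    for atoms in by_residue.values():
        root = atoms[0].serial
        for a in atoms[1:]:
            parent[find(a.serial)] = find(root)
    # CONECT between HET atoms merges groups
    for s1, s2 in model.conect:
        if s1 in by_serial and s2 in by_serial:
            parent[find(s1)] = find(s2)
    covalent_roots = set()
    for s1, s2 in model.conect:
        if s1 in by_serial and s2 in antibody_serials:
            covalent_roots.add(find(s1))
        elif s2 in by_serial and s1 in antibody_serials:
            covalent_roots.add(find(s2))
    groups: dict = {}
    for a in het_atoms:
        groups.setdefault(find(a.serial), []).append(a)
    out = []
    for root in sorted(groups):
        atoms = groups[root]
        lead = min(atoms, key=lambda a: a.serial)
        gid = (lead.res_name, lead.chain_label, lead.res_seq, lead.i_code)
        out.append(HetGroup(group_id=gid, atoms=atoms,
                            covalent_to_antibody=root in covalent_roots))
    return out


def classify_het_antigen(ab_set: AbAgSet, group: HetGroup,
                         model: pdbio.StructureModel,
                         params: PipelineParams | None = None,
                         table: SchemeTable | None = None) -> str:
    """antigen | none for one HETATM group against a currently free antibody."""
    params = params or PipelineParams()
    if group.covalent_to_antibody:
        return "none"
    prof = cdr_contact_profile(ab_set, group.atoms, str(group.group_id), params, table)
    if prof.cdr_contacts >= params.het_min_cdr_contacts:
        return "antigen"
    return "none"


def _antibody_sequence(ab_set: AbAgSet) -> str:
    return "|".join(ab_set.numbered[lbl].sequence for lbl in sorted(ab_set.numbered))


def resolve_anti_idiotype(sets: list, model: pdbio.StructureModel,
                          params: PipelineParams | None = None,
                          table: SchemeTable | None = None) -> list:
    """Screen a multi-antibody, antigen-free entry for antibody/antibody binding.

    Identical-sequence copies stay free.  Otherwise each antibody is offered
    in turn as a two-chain antigen of every other; when the CDR-contact rule
    passes, the receiving antibody becomes a protein complex whose antigen is
    the partner antibody's original chains.
    """
    params = params or PipelineParams()
    if len(sets) < 2:
        return sets
    seqs = {id(s): _antibody_sequence(s) for s in sets}
    if len(set(seqs.values())) == 1:
        return sets
    for s in sets:
        for other in sets:
            if other is s or seqs[id(other)] == seqs[id(s)]:
                continue
            partner_atoms = [a for a in other.antibody_atoms if not a.is_hydrogen]
            verdict = classify_polymer_antigen(
                s, "+".join(sorted(other.antibody_chain_map.values())),
                model, params, table, partner_atoms=partner_atoms)
            if verdict == "antigen":
                orig_chains = sorted(other.antibody_chain_map.values())
                ag_atoms = []
                for ch in orig_chains:
                    ag_atoms.extend(model.chain_atoms(ch))
                s.antigen_chains = orig_chains
                s.antigen_atoms = ag_atoms
                s.antigen_kind = "protein"
                break
    return sets


def finalize_complex_class(ab_set: AbAgSet) -> str:
    """free | protein | non_protein; mixed protein+HETATM antigens count as protein."""
    if ab_set.antigen_kind == "none":
        ab_set.complex_class = "free"
    elif ab_set.antigen_kind == "protein":
        ab_set.complex_class = "protein"
    else:  # nucleic or het
        ab_set.complex_class = "non_protein"
    return ab_set.complex_class
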