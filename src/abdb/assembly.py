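"""Pairing antibody chains and splitting entries into antibody/antigen sets.

Complete antibodies are assembled by pairing light and heavy chains where the
number of inter-chain atomic contacts (atom centres within 4 Å, hydrogens
excluded) is maximal — a greedy matching on the contact matrix, which
reproduces the near-block-diagonal structure of real multi-copy entries.
Light-chain dimers are paired geometrically instead: the Cα atoms of
positions L36 and of L87 of the two chains must each lie within 20 Å,
reconstructing the partner chain from crystal symmetry first when only one
copy is present in the deposited file.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import pdbio
from .params import PipelineParams


class PairingError(ValueError):
    """No physically plausible chain pairing exists."""


@dataclass(frozen=True)
class ContactCount:
    chain_a: str
    chain_b: str
    n_contacts: int
    cutoff: float = 4.0


@dataclass
class AbAgSet:
    """One antibody (1 or 2 chains) plus zero or one antigen.

    ``antibody_atoms`` hold the Kabat-renumbered Fv coordinates used by the
    geometric rules; per-scheme output coordinates are regenerated at write
    time.  ``antigen_atoms`` keep their original chain labels (lowered to
    l/h on collision only when the file is written).
    """
    set_id: str
    entry_code: str
    form: str                       # complete | light_only | heavy_only
    antibody_chain_map: dict        # new label (L/H/M) -> original chain label
    numbered: dict                  # new label -> NumberedChain (contact scheme)
    antibody_atoms: list            # renumbered AtomRecords, contact scheme
    antigen_chains: list = field(default_factory=list)  # original labels
    antigen_atoms: list = field(default_factory=list)
    antigen_kind: str = "none"      # none | protein | nucleic | het
    het_group: object = None
    complex_class: str = "free"     # free | protein | non_protein
    binding_proteins: list = field(default_factory=list)  # framework-only binders

    @property
    def roles(self) -> dict:
        """Output chain label -> role letter (the dimer's second chain M is a light)."""
        return {lbl: ("L" if lbl in ("L", "M") else "H") for lbl in self.antibody_chain_map}


def _heavy_coords(atoms: list) -> np.ndarray:
    pts = [(a.x, a.y, a.z) for a in atoms if not a.is_hydrogen]
    return np.asarray(pts, dtype=float).reshape(-1, 3)


def count_contacts_atoms(atoms_a: list, atoms_b: list, cutoff: float = 4.0) -> int:
    """Exact number of non-hydrogen atom pairs with centres within ``cutoff`` Å."""
    a, b = _heavy_coords(atoms_a), _heavy_coords(atoms_b)
    if len(a) == 0 or len(b) == 0:
        return 0
    return int(cKDTree(a).count_neighbors(cKDTree(b), cutoff))


def count_contacts(model: pdbio.StructureModel, chain_a: str, chain_b: str,
                   cutoff: float = 4.0) -> ContactCount:
    """Contacts between the polymer atoms of two chains of a model."""
    n = count_contacts_atoms(model.chain_atoms(chain_a), model.chain_atoms(chain_b), cutoff)
    return ContactCount(chain_a, chain_b, n, cutoff)


def pair_from_contact_matrix(contacts: list) -> list:
    """Greedy maximum-contact matching over (light, heavy) ContactCounts.

    Repeatedly takes the unused pair with the most contacts; zero-contact
    pairs are never formed; ties break on (light label, heavy label).
    """
    order = sorted(contacts, key=lambda c: (-c.n_contacts, c.chain_a, c.chain_b))
    used_l, used_h, pairs = set(), set(), []
    for c in order:
        if c.n_contacts <= 0:
            continue
        if c.chain_a in used_l or c.chain_b in used_h:
            continue
        used_l.add(c.chain_a)
        used_h.add(c.chain_b)
        pairs.append((c.chain_a, c.chain_b))
    if not pairs:
        raise PairingError("no physical pairing: all light/heavy contact counts are zero")
    return pairs


def pair_light_heavy(model: pdbio.StructureModel, lights: list, heavies: list,
                     params: PipelineParams | None = None,
                     atoms_by_chain: dict | None = None) -> list:
    """Pair light with heavy chains by maximal contact count.

    ``atoms_by_chain`` may supply pre-extracted (e.g. Fv-only) atoms keyed by
    chain label; otherwise whole-chain polymer atoms are used.
    """
    params = params or PipelineParams()
    if not lights or not heavies:
        raise PairingError("need at least one light and one heavy chain")

    def chain_atoms(ch):
        if atoms_by_chain is not None:
            return atoms_by_chain[ch]
        return model.chain_atoms(ch)

    contacts = [ContactCount(l, h,
                             count_contacts_atoms(chain_atoms(l), chain_atoms(h),
                                                  params.contact_cutoff),
                             params.contact_cutoff)
                for l in lights for h in heavies]
    return pair_from_contact_matrix(contacts)


def _ca_of(atoms: list, res_seq: int) -> np.ndarray | None:
    for a in atoms:
        if a.name == "CA" and a.res_seq == res_seq and not a.i_code:
            return a.coord
    return None


def pair_light_dimer(model: pdbio.StructureModel, lights: list,
                     params: PipelineParams | None = None,
                     atoms_by_chain: dict | None = None) -> list:
    """Pair light chains into dimers via the L36/L87 Cα proximity rule.

    Chains must already carry Kabat numbering (residue 36 and 87 resolvable).
    A pair forms when both the L36–L36 and L87–L87 Cα distances are within
    the cutoff; with more than two chains the closest distance-sum wins and
    each chain joins at most one pair.
    """
    params = params or PipelineParams()

    def chain_atoms(ch):
        if atoms_by_chain is not None:
            return atoms_by_chain[ch]
        return model.chain_atoms(ch)

    marks = {}
    for ch in lights:
        atoms = chain_atoms(ch)
        ca36, ca87 = _ca_of(atoms, 36), _ca_of(atoms, 87)
        if ca36 is None or ca87 is None:
            import logging
            logging.getLogger(__name__).warning(
                "chain %s: Cα of L36/L87 not observed; excluded from dimer pairing", ch)
            continue
        marks[ch] = (ca36, ca87)
    candidates = []
    keys = sorted(marks)
    for i, ci in enumerate(keys):
        for cj in keys[i + 1:]:
            d36 = float(np.linalg.norm(marks[ci][0] - marks[cj][0]))
            d87 = float(np.linalg.norm(marks[ci][1] - marks[cj][1]))
            if d36 <= params.dimer_ca_cutoff and d87 <= params.dimer_ca_cutoff:
                candidates.append((d36 + d87, ci, cj))
    candidates.sort()
    used, pairs = set(), []
    for _, ci, cj in candidates:
        if ci in used or cj in used:
            continue
        used.update((ci, cj))
        pairs.append((ci, cj))
    return pairs


def split_entry(entry_code: str, antibodies: list) -> list:
    """Assign set ids, ordering antibodies by their original chain labels.

    ``antibodies`` are AbAgSets with empty set ids.  A shared antigen has
    already been replicated into each antibody's set by antigen assignment,
    so splitting reduces to deterministic ordinal assignment (starting at 1).
    """
    ordered = sorted(antibodies, key=lambda s: tuple(sorted(s.antibody_chain_map.values())))
    for i, s in enumerate(ordered, start=1):
        s.set_id = f"{entry_code}_{i}"
    return ordered
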