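"""Contact counting, chain pairing and entry splitting."""
import random

import numpy as np
import pytest

from abdb import assembly, pdbio, pipeline
from abdb.assembly import (ContactCount, PairingError, count_contacts_atoms,
                           pair_from_contact_matrix, pair_light_dimer)
from abdb.fixtures import FixtureSpec, make_entry, make_fv_coordinates
from abdb.params import PipelineParams


def _atoms(points, chain="A", element="C"):
    return [pdbio.AtomRecord(i + 1, "C", "", "UNK", chain, i + 1, "",
                             float(x), float(y), float(z), 1.0, 0.0, element, False)
            for i, (x, y, z) in enumerate(points)]


def brute_force_contacts(atoms_a, atoms_b, cutoff):
    """Independent all-pairs oracle for the contact count."""
    n = 0
    for a in atoms_a:
        if a.is_hydrogen:
            continue
        for b in atoms_b:
            if b.is_hydrogen:
                continue
            d = ((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2) ** 0.5
            if d <= cutoff:
                n += 1
    return n


class TestCountContacts:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = _atoms(rng.uniform(0, 12, size=(25, 3)))
        b = _atoms(rng.uniform(0, 12, size=(25, 3)), chain="B")
        assert count_contacts_atoms(a, b, 4.0) == brute_force_contacts(a, b, 4.0)

    def test_far_apart_chains_have_zero(self):
        a = _atoms([(0, 0, 0), (1, 0, 0)])
        b = _atoms([(100, 0, 0)], chain="B")
        assert count_contacts_atoms(a, b, 4.0) == 0

    def test_hydrogens_excluded(self):
        a = _atoms([(0, 0, 0)])
        b = _atoms([(1, 0, 0)], chain="B", element="H")
        assert count_contacts_atoms(a, b, 4.0) == 0

    def test_cutoff_is_inclusive(self):
        a = _atoms([(0, 0, 0)])
        b = _atoms([(4.0, 0, 0)], chain="B")
        assert count_contacts_atoms(a, b, 4.0) == 1

    def test_empty_chain_counts_zero(self):
        assert count_contacts_atoms([], _atoms([(0, 0, 0)]), 4.0) == 0


class TestPairing:
    def test_published_anti_idiotype_contact_matrix(self):
        """Light A: 128 contacts with heavy B, 20 with D; light C: 10 with B,
        117 with D => antibodies (A,B) and (C,D)."""
        contacts = [ContactCount("A", "B", 128), ContactCount("A", "D", 20),
                    ContactCount("C", "B", 10), ContactCount("C", "D", 117)]
        assert pair_from_contact_matrix(contacts) == [("A", "B"), ("C", "D")]

    def test_zero_matrix_raises(self):
        with pytest.raises(PairingError):
            pair_from_contact_matrix([ContactCount("A", "B", 0)])

    def test_single_pair(self):
        assert pair_from_contact_matrix([ContactCount("L", "H", 30)]) == [("L", "H")]

    def test_three_copies_pair_block_diagonally(self):
        text = make_entry(FixtureSpec(code="3CPY", n_antibodies=3))
        res = pipeline.process_entry("3CPY", text)
        pairs = {tuple(sorted(s.antibody_chain_map.values())) for s in res.sets}
        assert pairs == {("H", "L"), ("K", "M"), ("C", "D")} == \
            {tuple(sorted(p)) for p in [("L", "H"), ("K", "M"), ("C", "D")]}

    def test_set_composition_invariant_under_file_order(self):
        a = pipeline.process_entry(
            "1AFX", make_entry(FixtureSpec(code="1AFX", n_antibodies=2,
                                           antigen="protein")))
        b = pipeline.process_entry(
            "1AFX", make_entry(FixtureSpec(code="1AFX", n_antibodies=2,
                                           antigen="protein", scramble_labels=True,
                                           seed=3)))
        comp = lambda res: {(tuple(sorted(s.antibody_chain_map.values())),
                             tuple(s.antigen_chains)) for s in res.sets}
        assert comp(a) == comp(b)


class TestLightDimer:
    def _dimer_atoms(self, separation):
        scaffold = make_fv_coordinates(
            seq_l=_light_consensus(), seq_h=None)
        atoms, numbered = scaffold["L"]
        def recs(offset_y, chain):
            out = []
            for i, (name, rn, rs, ic, x, y, z, el, het) in enumerate(atoms):
                out.append(pdbio.AtomRecord(i + 1, name, "", rn, chain,
                                            rs, ic, x, y + offset_y, z, 1.0, 0.0,
                                            el, het))
            return out
        # renumbered atom lists keyed by chain: resseq already 1..n; map to
        # kabat numbers via the numbering
        num_of = {i + 1: r.number for i, r in enumerate(numbered.residues)}
        def renum(rs_atoms):
            return [pdbio.AtomRecord(a.serial, a.name, "", a.res_name,
                                     a.chain_label, num_of[a.res_seq], "",
                                     a.x, a.y, a.z, 1.0, 0.0, a.element, False)
                    for a in rs_atoms]
        return {"A": renum(recs(0.0, "A")), "B": renum(recs(separation, "B"))}

    def test_dimer_within_cutoff_pairs(self):
        atoms = self._dimer_atoms(15.0)
        pairs = pair_light_dimer(None, ["A", "B"], PipelineParams(),
                                 atoms_by_chain=atoms)
        assert pairs == [("A", "B")]

    def test_dimer_beyond_cutoff_rejected(self):
        atoms = self._dimer_atoms(50.0)
        assert pair_light_dimer(None, ["A", "B"], PipelineParams(),
                                atoms_by_chain=atoms) == []

    def test_missing_l36_skips_pair(self):
        atoms = self._dimer_atoms(15.0)
        atoms["A"] = [a for a in atoms["A"] if a.res_seq != 36]
        assert pair_light_dimer(None, ["A", "B"], PipelineParams(),
                                atoms_by_chain=atoms) == []

    def test_biomt_partner_pairs_with_generator(self):
        text = make_entry(FixtureSpec(code="1BIO", form="light_only",
                                      light_dimer_via_biomt=True))
        res = pipeline.process_entry("1BIO", text)
        assert len(res.sets) == 1
        s = res.sets[0]
        assert s.form == "light_only"
        assert len(s.antibody_chain_map) == 2
        assert "L" in s.antibody_chain_map.values()


def _light_consensus():
    from abdb.numbering import load_scheme_table
    return load_scheme_table().template["L"]


class TestSplitEntry:
    def test_two_copy_entry_gives_two_sets(self):
        text = make_entry(FixtureSpec(code="1AFX", n_antibodies=2, antigen="protein"))
        res = pipeline.process_entry("1AFX", text)
        assert [s.set_id for s in res.sets] == ["1AFX_1", "1AFX_2"]
        assert {tuple(s.antigen_chains) for s in res.sets} == {("A",), ("B",)}

    def test_shared_antigen_replicated_into_each_set(self):
        text = make_entry(FixtureSpec(code="3ULX", n_antibodies=3, distinct=True,
                                      antigen="shared_protein"))
        res = pipeline.process_entry("3ULX", text)
        assert [s.set_id for s in res.sets] == ["3ULX_1", "3ULX_2", "3ULX_3"]
        assert all(s.antigen_chains == ["A"] for s in res.sets)

    def test_free_entry_single_set_without_antigen(self):
        res = pipeline.process_entry("1FRE", make_entry(FixtureSpec(code="1FRE")))
        assert len(res.sets) == 1
        s = res.sets[0]
        assert s.antigen_chains == [] and s.complex_class == "free"
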