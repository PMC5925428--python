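"""Scheme numbering: canonical labels, insertions, trimming, CDR lookup."""
import random

import pytest

from abdb import numbering, pdbio
from abdb.fixtures import FixtureSpec, make_entry
from abdb.numbering import (NumberingFailure, cdr_membership, number_chain,
                            renumber_structure)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _mutate(seq, n, rng):
    out = list(seq)
    for i in rng.sample(range(len(seq)), n):
        out[i] = rng.choice([c for c in AA if c != out[i]])
    return "".join(out)


class TestNumberChain:
    def test_canonical_light_is_l1_to_l107(self, profile, table):
        for scheme in numbering.SCHEMES:
            nc = number_chain(profile.light_consensus, "L", scheme, table)
            assert nc.labels == [f"L{i}" for i in range(1, 108)]

    def test_canonical_heavy_includes_82abc(self, profile, table):
        nc = number_chain(profile.heavy_consensus, "H", "kabat", table)
        assert len(nc.residues) == 116
        assert [l for l in nc.labels if l.startswith("H82")] == \
            ["H82", "H82A", "H82B", "H82C"]
        assert nc.labels[-1] == "H113"

    def test_cdr_l1_insertion_site_differs_by_scheme(self, profile, table):
        seq = profile.light_consensus[:28] + "GS" + profile.light_consensus[28:]
        expected = {"kabat": ["L27A", "L27B"],
                    "chothia": ["L30A", "L30B"],
                    "martin": ["L30A", "L30B"]}
        for scheme, ins in expected.items():
            nc = number_chain(seq, "L", scheme, table)
            got = [l for l in nc.labels if l[-1].isalpha() and l not in
                   ("L82A", "L82B", "L82C")]
            assert got == ins
            # 13 residues now span CDR-L1 (24-34 plus two insertions)
            assert len(nc.residues) == 109

    def test_cdr_h3_insertions_at_100(self, profile, table):
        seq = profile.heavy_consensus[:100] + "YYY" + profile.heavy_consensus[100:]
        nc = number_chain(seq, "H", "kabat", table)
        extra = [l for l in nc.labels if l[-1].isalpha()
                 and l not in ("H82A", "H82B", "H82C")]
        assert extra == ["H100A", "H100B", "H100C"]

    def test_short_cdr_skips_labels_after_anchor(self, profile, table):
        seq = profile.light_consensus[:90] + profile.light_consensus[93:]
        nc = number_chain(seq, "L", "kabat", table)
        nums = {l for l in nc.labels}
        assert "L89" in nums and "L98" in nums
        assert len([l for l in nums if l.startswith("L9") and len(l) == 3]) < 9

    def test_random_sequences_fail_cleanly(self, table):
        rng = random.Random(11)
        for _ in range(20):
            seq = "".join(rng.choice(AA) for _ in range(120))
            assert number_chain(seq, "L", "kabat", table) is None
            assert number_chain(seq, "H", "martin", table) is None

    def test_constant_domain_and_leader_trimmed(self, profile, table):
        leader = "MGWSCIILFLVATATGVHS"
        ch1 = "AKTTPPSVYPLAPGSAAQTNSMVTLGCLVKGYFPEPVTVTW"
        nc = number_chain(leader + profile.light_consensus + ch1, "L", "kabat", table)
        assert len(nc.residues) == 107
        assert nc.sequence == profile.light_consensus

    def test_bad_role_and_scheme_raise(self, table):
        with pytest.raises(ValueError):
            number_chain("ACD", "X", "kabat", table)
        with pytest.raises(ValueError):
            number_chain("ACD", "L", "imgt", table)


def test_numbering_bijection_roundtrip(profile, table):
    """Labels are unique, ordered, and map back to the exact input residues."""
    rng = random.Random(5)
    for role, cons in (("L", profile.light_consensus), ("H", profile.heavy_consensus)):
        for _ in range(15):
            seq = _mutate(cons, rng.randint(0, 12), rng)
            if rng.random() < 0.5:  # indel variants
                i = rng.randint(25, 30)
                seq = seq[:i] + "GS" + seq[i:]
            for scheme in numbering.SCHEMES:
                nc = number_chain(seq, role, scheme, table)
                assert nc is not None
                assert len(set(nc.labels)) == len(nc.labels)
                idx = [r.seq_index for r in nc.residues]
                assert idx == sorted(idx)
                assert all(seq[r.seq_index] == r.aa for r in nc.residues)


def test_schemes_agree_without_insertions(profile, table):
    for role, cons in (("L", profile.light_consensus), ("H", profile.heavy_consensus)):
        labelsets = {s: number_chain(cons, role, s, table).labels
                     for s in numbering.SCHEMES}
        assert labelsets["kabat"] == labelsets["chothia"] == labelsets["martin"]


class TestCdrMembership:
    @pytest.mark.parametrize("label,role,expected", [
        ("L24", "L", "CDR-L1"),
        ("L36", "L", "framework"),
        ("L50", "L", "CDR-L2"),
        ("L89", "L", "CDR-L3"),
        ("H100A", "H", "CDR-H3"),
        ("H31", "H", "CDR-H1"),
        ("H82A", "H", "framework"),
    ])
    def test_kabat_lookup(self, table, label, role, expected):
        for scheme in numbering.SCHEMES:
            assert cdr_membership(label, role, scheme, table) == expected

    def test_chothia_definition_differs(self, table):
        assert cdr_membership("H31", "H", "kabat", table, definition="chothia") == "CDR-H1"
        assert cdr_membership("H50", "H", "kabat", table, definition="chothia") == "framework"

    def test_invalid_label_raises(self, table):
        with pytest.raises(ValueError):
            cdr_membership("L999", "L", "kabat", table)
        with pytest.raises(ValueError):
            cdr_membership("banana", "L", "kabat", table)


class TestRenumberStructure:
    def test_fv_only_chain_keeps_all_atoms(self, table):
        model = pdbio.parse_pdb(make_entry(FixtureSpec(code="1FRE")))
        seq = pdbio.sequence_from_atoms(model, "L")
        nc = number_chain(seq, "L", "kabat", table)
        atoms = renumber_structure(model, "L", nc, "L")
        assert len(atoms) == len(model.chain_atoms("L"))
        assert {a.chain_label for a in atoms} == {"L"}
        assert max(a.res_seq for a in atoms) == 107

    def test_constant_domain_atoms_dropped(self, table, profile):
        """A Fab-like chain loses its CH1 atoms; last label is the Fv end."""
        model = pdbio.parse_pdb(make_entry(FixtureSpec(code="1FRE")))
        seq = pdbio.sequence_from_atoms(model, "H")
        fab_seq = seq + "AKTTPPSVYPLAPGSAAQT"
        nc = number_chain(fab_seq, "H", "kabat", table)
        assert len(nc.residues) == 116  # constant part trimmed at numbering
        atoms = renumber_structure(model, "H", nc, "H")
        assert len(atoms) == len(model.chain_atoms("H"))

    def test_unobserved_cdr_numbered_from_seqres(self, table):
        """SEQRES numbers everything; atoms exist only for observed residues."""
        text = make_entry(FixtureSpec(code="1FRE"))
        # drop the coordinates of heavy CDR-H3 residues (resseq 99-106 in file space)
        lines = [l for l in text.splitlines()
                 if not (l.startswith("ATOM") and l[21] == "H"
                         and 99 <= int(l[22:26]) <= 103)]
        model = pdbio.parse_pdb("\n".join(lines))
        seq = model.seqres["H"]
        nc = number_chain(seq, "H", "kabat", table)
        assert len(nc.residues) == 116
        atoms = renumber_structure(model, "H", nc, "H")
        observed = {(a.res_seq, a.i_code) for a in atoms}
        assert len(observed) == 116 - 5

    def test_interior_unmappable_residue_rejects(self, table, profile):
        model = pdbio.parse_pdb(make_entry(FixtureSpec(code="1FRE")))
        # number a sequence missing an interior stretch the structure observes
        seq = pdbio.sequence_from_atoms(model, "L")
        nc = number_chain(seq[:40] + seq[60:], "L", "kabat", table)
        with pytest.raises(NumberingFailure):
            renumber_structure(model, "L", nc, "L")
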