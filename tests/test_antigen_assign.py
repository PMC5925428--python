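"""Antigen classification rules: CDR dominance, haptens, anti-idiotypes."""
import random

import pytest

from abdb import antigen_assign, pdbio, pipeline
from abdb.antigen_assign import (HetGroup, cdr_contact_profile,
                                 classify_het_antigen, classify_polymer_antigen,
                                 collect_het_groups, finalize_complex_class)
from abdb.assembly import AbAgSet
from abdb.fixtures import FixtureSpec, make_entry
from abdb.params import PipelineParams


def _atom(serial, chain, res_seq, x, y, z, name="C", res_name="ALA", het=False):
    return pdbio.AtomRecord(serial, name, "", res_name, chain, res_seq, "",
                            float(x), float(y), float(z), 1.0, 0.0, name[0], het)


def _ab_with_sites(n_cdr=20, n_fw=20):
    """Antibody stub: isolated CDR atoms (L24) and framework atoms (L36).

    Sites are 10 Å apart so a partner atom placed 3 Å above one site contacts
    exactly that site.
    """
    atoms = []
    s = 0
    for i in range(n_cdr):
        s += 1
        atoms.append(_atom(s, "L", 24, i * 10.0, 0.0, 0.0))
    for i in range(n_fw):
        s += 1
        atoms.append(_atom(s, "L", 36, 1000.0 + i * 10.0, 0.0, 0.0))
    return AbAgSet(set_id="X_1", entry_code="X", form="light_only",
                   antibody_chain_map={"L": "A"}, numbered={},
                   antibody_atoms=atoms)


def _partner(n_at_cdr, n_at_fw, chain="P"):
    pts = [(i * 10.0, 0.0, 3.0) for i in range(n_at_cdr)]
    pts += [(1000.0 + i * 10.0, 0.0, 3.0) for i in range(n_at_fw)]
    return [_atom(500 + i, chain, i + 1, *p) for i, p in enumerate(pts)]


class TestPolymerRule:
    def test_profile_counts_are_exact(self, params):
        ab = _ab_with_sites()
        prof = cdr_contact_profile(ab, _partner(7, 3), "P", params)
        assert (prof.cdr_contacts, prof.framework_contacts) == (7, 3)

    @pytest.mark.parametrize("cdr,fw,expected", [
        (20, 3, "antigen"),            # dominant CDR binding, >= 15 contacts
        (10, 3, "antibody_binding_protein"),   # too few CDR contacts
        (16, 20, "antibody_binding_protein"),  # framework-dominated (SpA-like)
        (0, 30, "antibody_binding_protein"),
        (0, 0, "unrelated"),
    ])
    def test_classification(self, params, cdr, fw, expected):
        ab = _ab_with_sites(n_cdr=max(cdr, 1), n_fw=max(fw, 1))
        verdict = classify_polymer_antigen(ab, "P", None, params,
                                           partner_atoms=_partner(cdr, fw))
        assert verdict == expected

    def test_raising_min_cdr_contacts_only_shrinks_antigens(self):
        ab = _ab_with_sites()
        partner = _partner(20, 3)
        verdicts = [classify_polymer_antigen(
            ab, "P", None, PipelineParams(min_cdr_contacts=t),
            partner_atoms=partner) for t in (5, 15, 21, 40)]
        assert verdicts == ["antigen", "antigen", "antibody_binding_protein",
                            "antibody_binding_protein"]

    def test_atom_order_does_not_change_outcome(self, params):
        ab = _ab_with_sites()
        partner = _partner(18, 4)
        rng = random.Random(0)
        for _ in range(3):
            rng.shuffle(partner)
            rng.shuffle(ab.antibody_atoms)
            prof = cdr_contact_profile(ab, partner, "P", params)
            assert (prof.cdr_contacts, prof.framework_contacts) == (18, 4)


class TestHetRule:
    def _group(self, covalent=False, at_cdr=True):
        x = 0.0 if at_cdr else 1000.0
        atoms = [_atom(900 + i, "L", 500, x + i * 0.5, 0.0, 3.0, res_name="HAP",
                       het=True) for i in range(3)]
        return HetGroup(group_id=("HAP", "L", 500, ""), atoms=atoms,
                        covalent_to_antibody=covalent)

    def test_cdr_contacting_hapten_is_antigen(self, params):
        assert classify_het_antigen(_ab_with_sites(), self._group(), None,
                                    params) == "antigen"

    def test_covalent_hapten_is_not_antigen(self, params):
        assert classify_het_antigen(_ab_with_sites(), self._group(covalent=True),
                                    None, params) == "none"

    def test_framework_only_glycan_is_not_antigen(self, params):
        assert classify_het_antigen(_ab_with_sites(), self._group(at_cdr=False),
                                    None, params) == "none"

    def test_water_never_forms_group(self):
        with pytest.raises(ValueError):
            HetGroup(("HOH", "A", 1, ""), [_atom(1, "A", 1, 0, 0, 0,
                                                 res_name="HOH", het=True)])

    def test_conect_grouping_and_covalency(self):
        text = make_entry(FixtureSpec(code="1COV", antigen="hapten_covalent"))
        model = pdbio.parse_pdb(text)
        ab_serials = {a.serial for ch in ("L", "H") for a in model.chain_atoms(ch)}
        groups = collect_het_groups(model, ab_serials)
        assert len(groups) == 1
        assert groups[0].covalent_to_antibody
        assert len(groups[0].atoms) == 5


class TestAntiIdiotype:
    def test_identical_copies_stay_free(self):
        text = make_entry(FixtureSpec(code="2CPY", n_antibodies=2))
        res = pipeline.process_entry("2CPY", text)
        assert [s.complex_class for s in res.sets] == ["free", "free"]

    def test_distinct_interacting_pair_yields_two_protein_sets(self):
        text = make_entry(FixtureSpec(code="1DVX", antigen="anti_idiotype"))
        res = pipeline.process_entry("1DVX", text)
        assert len(res.sets) == 2
        assert all(s.complex_class == "protein" for s in res.sets)
        # each antibody's chains reappear as the other's antigen
        ab = [tuple(sorted(s.antibody_chain_map.values())) for s in res.sets]
        ag = [tuple(s.antigen_chains) for s in res.sets]
        assert set(ab) == set(ag)
        assert ab[0] == ag[1] and ab[1] == ag[0]

    def test_distinct_but_not_touching_stay_free(self):
        text = make_entry(FixtureSpec(code="2FAR", n_antibodies=2, distinct=True))
        res = pipeline.process_entry("2FAR", text)
        assert [s.complex_class for s in res.sets] == ["free", "free"]


class TestComplexClass:
    def _set(self, kind):
        s = _ab_with_sites()
        s.antigen_kind = kind
        return s

    @pytest.mark.parametrize("kind,expected", [
        ("none", "free"), ("protein", "protein"),
        ("nucleic", "non_protein"), ("het", "non_protein"),
    ])
    def test_mapping(self, kind, expected):
        assert finalize_complex_class(self._set(kind)) == expected

    def test_dna_entry_lands_in_non_protein(self):
        res = pipeline.process_entry(
            "3VWX", make_entry(FixtureSpec(code="3VWX", antigen="dna")))
        assert res.sets[0].complex_class == "non_protein"
        assert res.sets[0].antigen_kind == "nucleic"

    def test_hapten_entry_lands_in_non_protein(self):
        res = pipeline.process_entry(
            "1HAP", make_entry(FixtureSpec(code="1HAP", antigen="hapten_free")))
        assert res.sets[0].complex_class == "non_protein"

    def test_covalent_hapten_entry_stays_free(self):
        res = pipeline.process_entry(
            "1COV", make_entry(FixtureSpec(code="1COV", antigen="hapten_covalent")))
        assert res.sets[0].complex_class == "free"

    def test_framework_binder_entry_stays_free(self):
        res = pipeline.process_entry(
            "1DEX", make_entry(FixtureSpec(code="1DEX", antigen="framework_binder")))
        s = res.sets[0]
        assert s.complex_class == "free"
        assert s.binding_proteins == ["A"]
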