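import copy

import numpy as np
import pytest

from ligsearch.fixtures import (ComplexSpec, PlantedInteraction, make_complex,
                                rigid_motion_from_seed)
from ligsearch.formats_io import Atom, LigandInstance, Residue, Structure, read_pdb
from ligsearch.interactions import (InteractionRecord, LigandScore,
                                    ScoringScheme, classify_conservation,
                                    detect_contacts, detect_hbonds,
                                    merge_domain_scores, score_ligand)


def _mini_structure(residue_specs):
    """Structure from [(seq_num, res_type, [(atom_name, element, xyz)])]."""
    residues = []
    serial = 0
    for seq_num, res_type, atoms in residue_specs:
        alist = []
        for name, element, xyz in atoms:
            serial += 1
            alist.append(Atom(name=name, element=element,
                              coords=np.array(xyz, dtype=float), serial=serial))
        residues.append(Residue(chain_id="A", seq_num=seq_num,
                                insertion_code="", res_type=res_type,
                                atoms=alist))
    return Structure(id="MINI", chains={"A": residues})


def _ligand(atoms, het="LIG"):
    return LigandInstance(structure_id="MINI", het_code=het, chain_id="A",
                          seq_num=900,
                          atoms=[Atom(name=n, element=e,
                                      coords=np.array(x, dtype=float),
                                      serial=500 + i)
                                 for i, (n, e, x) in enumerate(atoms)])


def _record(kind, conservation, seq_num=1, distance=3.0):
    res = Residue(chain_id="A", seq_num=seq_num, insertion_code="",
                  res_type="ALA", atoms=[])
    atom = Atom(name="O1", element="O", coords=np.zeros(3))
    return InteractionRecord(ligand_atom=atom, protein_residue=res, kind=kind,
                             distance=distance, conservation=conservation)


class TestDetectHbonds:
    def test_polar_pair_within_threshold(self, scheme):
        st = _mini_structure([(1, "ALA", [("N", "N", (0, 0, 0))])])
        lig = _ligand([("O1", "O", (3.0, 0, 0))])
        records = detect_hbonds(st, lig, scheme)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(3.0)

    def test_carbon_is_not_polar(self, scheme):
        st = _mini_structure([(1, "ALA", [("O", "O", (0, 0, 0))])])
        lig = _ligand([("C1", "C", (3.0, 0, 0))])
        assert detect_hbonds(st, lig, scheme) == []

    def test_planted_fixture_recovered_exactly(self, planted_complex, scheme):
        st, truth = planted_complex
        records = detect_hbonds(st, st.ligands[0], scheme)
        got = sorted((r.protein_residue.seq_num, r.ligand_atom.name)
                     for r in records)
        assert got == sorted((i, n) for i, n, _ in truth["hbonds"])


class TestDetectContacts:
    def test_several_contacts_to_one_residue_count_once(self, scheme):
        atoms = [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0)),
                 ("CG", "C", (3.0, 0, 0))]
        st = _mini_structure([(1, "LEU", atoms)])
        lig = _ligand([("C1", "C", (0, 3.5, 0))])
        records = detect_contacts(st, lig, scheme)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(3.5)   # closest pair kept

    def test_hbonded_residue_accrues_no_contact(self, scheme):
        atoms = [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0))]
        st = _mini_structure([(1, "GLY", atoms)])
        lig = _ligand([("O1", "O", (3.0, 0, 0))])
        hb = detect_hbonds(st, lig, scheme)
        assert len(hb) == 1
        assert detect_contacts(st, lig, scheme, hbonds=hb) == []

    def test_empty_when_nothing_in_range(self, scheme):
        st = _mini_structure([(1, "ALA", [("CA", "C", (0, 0, 0))])])
        lig = _ligand([("C1", "C", (50, 0, 0))])
        assert detect_contacts(st, lig, scheme) == []


class TestClassifyConservation:
    @pytest.mark.parametrize("hit_res,query_aa,expected", [
        ("ARG", "R", "identical"),
        ("LYS", "R", "similar"),     # BLOSUM62 R/K = +2
        ("ASP", "R", "other"),       # BLOSUM62 R/D = -2
    ])
    def test_classes_from_matrix(self, hit_res, query_aa, expected):
        record = _record("hbond", None, seq_num=5)
        record.protein_residue.res_type = hit_res
        hit_seq = "AAAA" + record.protein_residue.one_letter + "AAA"
        query_seq = "AAAA" + query_aa + "AAA"
        cls = classify_conservation(record, hit_pos=5,
                                    query_to_hit={i: i for i in range(1, 9)},
                                    query_seq=query_seq, hit_seq=hit_seq)
        assert cls == expected
        assert record.conservation == expected

    def test_unaligned_insertion_is_gap(self):
        record = _record("contact", None, seq_num=5)
        cls = classify_conservation(record, hit_pos=5,
                                    query_to_hit={1: 1, 2: 2},   # 5 unaligned
                                    query_seq="AA", hit_seq="AAAAA")
        assert cls == "gap"

    def test_residue_outside_entry_is_gap(self):
        record = _record("hbond", None)
        assert classify_conservation(record, hit_pos=None, query_to_hit={},
                                     query_seq="A", hit_seq="A") == "gap"


class TestScoreLigand:
    def test_no_interactions_scores_zero_over_zero(self, scheme):
        lig = _ligand([("C1", "C", (0, 0, 0))])
        score = score_ligand(lig, [], [], scheme)
        assert (score.achieved, score.maximum) == (0, 0)

    def test_quoted_weights_sum(self, scheme):
        """H-bonds to identical/similar/gap plus contacts to identical/gap."""
        lig = _ligand([("O1", "O", (0, 0, 0))])
        hbonds = [_record("hbond", c, seq_num=i + 1)
                  for i, c in enumerate(["identical", "similar", "gap"])]
        contacts = [_record("contact", c, seq_num=i + 10)
                    for i, c in enumerate(["identical", "gap"])]
        score = score_ligand(lig, hbonds, contacts, scheme)
        assert score.achieved == 3 + 2 - 1 + 2 - 1 == 5
        assert score.maximum == 3 * 3 + 2 * 2 == 13
        assert score.as_fraction == "5/13"

    def test_unclassified_record_rejected(self, scheme):
        lig = _ligand([("O1", "O", (0, 0, 0))])
        with pytest.raises(ValueError):
            score_ligand(lig, [_record("hbond", None)], [], scheme)

    def test_all_identical_achieves_ceiling(self, scheme):
        lig = _ligand([("O1", "O", (0, 0, 0))])
        hbonds = [_record("hbond", "identical", seq_num=i) for i in range(1, 5)]
        contacts = [_record("contact", "identical", seq_num=i)
                    for i in range(10, 13)]
        score = score_ligand(lig, hbonds, contacts, scheme)
        assert score.achieved == score.maximum == 3 * 4 + 2 * 3

    def test_upgrading_conservation_never_decreases_achieved(self, scheme):
        lig = _ligand([("O1", "O", (0, 0, 0))])
        order = ["gap", "other", "similar", "identical"]
        prev = None
        for cls in order:
            score = score_ligand(lig, [_record("hbond", cls)],
                                 [_record("contact", cls, seq_num=2)], scheme)
            if prev is not None:
                assert score.achieved >= prev
            prev = score.achieved

    def test_score_invariant_under_rigid_motion(self, scheme):
        spec = ComplexSpec(seed=13, n_residues=30, interactions=[
            PlantedInteraction(5, "hbond"), PlantedInteraction(20, "contact")])
        text, _ = make_complex(spec)
        moved = ComplexSpec(seed=13, n_residues=30, interactions=[
            PlantedInteraction(5, "hbond"), PlantedInteraction(20, "contact")],
            rigid_motion=rigid_motion_from_seed(3))
        text2, _ = make_complex(moved)
        for t in (text, text2):
            st = read_pdb(t, structure_id="S")
            hb = detect_hbonds(st, st.ligands[0], scheme)
            ct = detect_contacts(st, st.ligands[0], scheme, hbonds=hb)
            assert (len(hb), len(ct)) == (1, 1)


class TestMergeDomainScores:
    def _score(self, lig, hbonds, contacts, scheme):
        return score_ligand(lig, hbonds, contacts, scheme)

    def test_single_domain_unchanged(self, scheme):
        lig = _ligand([("O1", "O", (0, 0, 0))])
        s = self._score(lig, [_record("hbond", "identical")], [], scheme)
        assert merge_domain_scores([s], scheme) is s

    def test_disjoint_domains_sum(self, scheme):
        lig = _ligand([("O1", "O", (0, 0, 0))])
        s1 = self._score(
            lig,
            [_record("hbond", c, seq_num=i + 1)
             for i, c in enumerate(["identical", "similar", "gap"])],
            [_record("contact", c, seq_num=i + 10)
             for i, c in enumerate(["identical", "gap"])], scheme)     # 5/13
        s2 = self._score(
            lig, [_record("hbond", "identical", seq_num=20)],
            [_record("contact", "similar", seq_num=21)], scheme)       # 4/5
        merged = merge_domain_scores([s1, s2], scheme)
        assert (merged.achieved, merged.maximum) == (9, 18)

    def test_shared_residue_counted_once(self, scheme):
        lig = _ligand([("O1", "O", (0, 0, 0))])
        s1 = self._score(lig, [], [_record("contact", "identical")], scheme)
        s2 = self._score(lig, [], [_record("contact", "identical")], scheme)
        merged = merge_domain_scores([s1, s2], scheme)
        assert (merged.achieved, merged.maximum) == (2, 2)

    def test_hbond_beats_contact_on_collision(self, scheme):
        lig = _ligand([("O1", "O", (0, 0, 0))])
        s1 = self._score(lig, [_record("hbond", "identical")], [], scheme)
        s2 = self._score(lig, [], [_record("contact", "identical")], scheme)
        merged = merge_domain_scores([s1, s2], scheme)
        assert (merged.achieved, merged.maximum) == (3, 3)

    def test_mixed_ligands_rejected(self, scheme):
        lig1 = _ligand([("O1", "O", (0, 0, 0))], het="AAA")
        lig2 = _ligand([("O1", "O", (0, 0, 0))], het="BBB")
        s1 = self._score(lig1, [_record("hbond", "identical")], [], scheme)
        s2 = self._score(lig2, [_record("hbond", "identical")], [], scheme)
        with pytest.raises(ValueError):
            merge_domain_scores([s1, s2], scheme)

    def test_removing_a_record_never_increases_maximum(self, scheme):
        lig = _ligand([("O1", "O", (0, 0, 0))])
        records = [_record("hbond", "identical", seq_num=i) for i in (1, 2)]
        contacts = [_record("contact", "other", seq_num=3)]
        full = self._score(lig, records, contacts, scheme)
        less = self._score(lig, records[:1], contacts, scheme)
        assert less.maximum <= full.maximum


def test_scheme_requires_decreasing_weights():
    with pytest.raises(ValueError):
        ScoringScheme(hb_identical=1, hb_similar=2)
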