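"""Restraint generation against brute-force oracles; keyword round-trip."""

import numpy as np
import pytest

from lorefine.homology import atom_pairing
from lorefine.model_io import Chain, Structure
from lorefine.restraints import (RestraintConfig, RestraintParseError,
                                 detect_mainchain_hbonds,
                                 generate_hbond_restraints,
                                 generate_homologue_restraints,
                                 generate_jelly_restraints,
                                 read_refmac_external,
                                 write_refmac_external)
from lorefine.synthetic import make_homologue, make_ideal_helix
from oracles import oracle_hbonds, oracle_homologue_pairs, oracle_jelly_pairs


def _as_pair_map(restraint_set):
    return {frozenset((r.atom_1, r.atom_2)): r.target_distance
            for r in restraint_set}


class TestHomologueRestraints:
    def test_matches_brute_force_enumeration(self, helix12):
        ref = make_homologue(helix12, 90, 0.2, seed=2)
        pairing = atom_pairing(helix12.chains[0], ref.chains[0])
        rs = generate_homologue_restraints(helix12, [(ref, pairing)])
        expected = oracle_homologue_pairs(helix12, ref, pairing)
        got = _as_pair_map(rs)
        assert got.keys() == expected.keys()
        for pair, d in expected.items():
            assert got[pair] == pytest.approx(d, abs=1e-9)

    def test_objective_is_the_reference_distance(self, helix12):
        ref = make_homologue(helix12, 100, 0.0, seed=0)
        pairing = atom_pairing(helix12.chains[0], ref.chains[0])
        rs = generate_homologue_restraints(helix12, [(ref, pairing)])
        index = ref.atom_index()
        for r in rs:
            d = np.linalg.norm(index[r.atom_1].xyz - index[r.atom_2].xyz)
            assert r.target_distance == pytest.approx(float(d), abs=1e-9)

    def test_pairs_beyond_cutoff_absent(self, helix12):
        ref = make_homologue(helix12, 100, 0.0, seed=0)
        pairing = atom_pairing(helix12.chains[0], ref.chains[0])
        rs = generate_homologue_restraints(helix12, [(ref, pairing)])
        index = ref.atom_index()
        emitted = {frozenset((r.atom_1, r.atom_2)) for r in rs}
        atoms = helix12.atoms()
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                d = np.linalg.norm(index[atoms[i].key].xyz
                                   - index[atoms[j].key].xyz)
                if d > 4.2:
                    assert frozenset((atoms[i].key, atoms[j].key)) \
                        not in emitted

    def test_covalently_bonded_pairs_excluded(self, helix12):
        ref = make_homologue(helix12, 100, 0.0, seed=0)
        pairing = atom_pairing(helix12.chains[0], ref.chains[0])
        emitted = {frozenset((r.atom_1, r.atom_2))
                   for r in generate_homologue_restraints(
                       helix12, [(ref, pairing)])}
        n = ("A", 1, "", "N")
        ca = ("A", 1, "", "CA")
        c = ("A", 1, "", "C")
        assert frozenset((n, ca)) not in emitted       # 1-2
        assert frozenset((n, c)) not in emitted        # 1-3

    def test_identical_copies_share_groups_with_k_alternatives(self, helix12):
        ref = make_homologue(helix12, 100, 0.1, seed=4)
        pairing = atom_pairing(helix12.chains[0], ref.chains[0])
        one = generate_homologue_restraints(helix12, [(ref, pairing)])
        three = generate_homologue_restraints(
            helix12, [(ref, pairing)] * 3)
        assert len(three) == 3 * len(one)
        assert len(three.by_group()) == len(one)
        assert all(len(g) == 3 for g in three.by_group().values())

    def test_empty_pairing_gives_empty_set(self, helix12):
        rs = generate_homologue_restraints(helix12, [(helix12, [])])
        assert len(rs) == 0

    def test_no_restraint_references_absent_atom(self, helix12):
        ref = make_homologue(helix12, 85, 0.3, seed=6)
        pairing = atom_pairing(helix12.chains[0], ref.chains[0])
        rs = generate_homologue_restraints(helix12, [(ref, pairing)])
        keys = set(helix12.atom_index())
        for r in rs:
            assert r.atom_1 in keys and r.atom_2 in keys


class TestHydrogenBonds:
    def test_helix_has_i_plus_4_pattern(self, helix12):
        bonds = detect_mainchain_hbonds(helix12)
        pattern = sorted((o.residue_seq, n.residue_seq) for n, o in bonds)
        assert pattern == [(i, i + 4) for i in range(1, 9)]

    def test_strand_has_no_bonds(self, strand12):
        assert detect_mainchain_hbonds(strand12) == []

    def test_sheet_bonds_match_all_pairs_oracle(self, sheet8):
        got = {(n.key, o.key) for n, o in detect_mainchain_hbonds(sheet8)}
        assert got == oracle_hbonds(sheet8)
        inter = [pair for pair in got if pair[0][0] != pair[1][0]]
        assert len(inter) >= 1

    def test_helix_bonds_match_all_pairs_oracle(self, helix12):
        got = {(n.key, o.key) for n, o in detect_mainchain_hbonds(helix12)}
        assert got == oracle_hbonds(helix12)

    def test_hbond_restraints_all_at_standard_length(self, helix12):
        rs = generate_hbond_restraints(helix12)
        assert len(rs) == 8
        assert all(r.target_distance == pytest.approx(2.8) for r in rs)
        assert all(r.source == "hbond" for r in rs)

    def test_restraint_count_equals_detection_count(self, helix12, strand12):
        mixed = Structure("mixed", [helix12.chains[0],
                                    Chain("B", [
                                        _shift_residue(r, 50.0)
                                        for r in strand12.chains[0].residues
                                    ])])
        assert len(generate_hbond_restraints(mixed)) == \
            len(detect_mainchain_hbonds(mixed))


def _shift_residue(residue, dx):
    from dataclasses import replace
    from lorefine.model_io import Residue
    atoms = [replace(a, pos=(a.pos[0] + dx, a.pos[1], a.pos[2]),
                     chain_id="B") for a in residue.atoms]
    return Residue(residue.name, residue.seq, residue.icode, "B", atoms)


class TestJellyRestraints:
    def test_self_restraints_have_zero_residual(self, helix12):
        rs = generate_jelly_restraints(helix12)
        index = helix12.atom_index()
        for r in rs:
            d = float(np.linalg.norm(index[r.atom_1].xyz
                                     - index[r.atom_2].xyz))
            assert r.target_distance == pytest.approx(d, abs=1e-9)

    def test_matches_brute_force_enumeration(self, helix12):
        got = _as_pair_map(generate_jelly_restraints(helix12))
        expected = oracle_jelly_pairs(helix12)
        assert got.keys() == expected.keys()

    def test_widely_separated_atoms_give_empty_set(self):
        helix = make_ideal_helix(3)
        atoms = helix.atoms()
        coords = np.array([a.xyz for a in atoms])
        # push the three residues 50 Å apart along x
        for i, a in enumerate(atoms):
            coords[i] += np.array([50.0 * (a.residue_seq - 1), 0.0, 0.0])
        spread = helix.copy_with_coords(coords, atoms)
        cfg = RestraintConfig()
        kept = [r for r in generate_jelly_restraints(spread, cfg)
                if r.atom_1[1] != r.atom_2[1]]
        assert kept == []


class TestSerialization:
    def test_roundtrip_is_field_identical(self, tmp_path, helix12):
        ref = make_homologue(helix12, 90, 0.2, seed=8)
        pairing = atom_pairing(helix12.chains[0], ref.chains[0])
        rs = generate_homologue_restraints(helix12, [(ref, pairing)] * 2)
        path = tmp_path / "ext.txt"
        write_refmac_external(rs, path)
        back = read_refmac_external(path)
        assert len(back) == len(rs)
        for a, b in zip(rs, back):
            assert (a.atom_1, a.atom_2, a.sigma, a.group_id, a.source) == \
                (b.atom_1, b.atom_2, b.sigma, b.group_id, b.source)
            assert b.target_distance == pytest.approx(a.target_distance,
                                                      abs=5e-4)

    def test_hbond_file_contains_standard_length(self, tmp_path, helix12):
        path = tmp_path / "hb.txt"
        write_refmac_external(generate_hbond_restraints(helix12), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 8
        assert all("value 2.800" in line for line in lines)
        assert all(line.startswith("exte dist first chain")
                   for line in lines)

    def test_missing_sigma_token_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(
            "exte dist first chain A resi 1 ins . atom O second chain A "
            "resi 5 ins . atom N value 2.800 type 0\n")
        with pytest.raises(RestraintParseError, match="sigma"):
            read_refmac_external(path)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad2.txt"
        path.write_text("exte dist first chain A resi 1 ins . atom O\n"
                        "not a restraint line\n")
        with pytest.raises(RestraintParseError, match="line"):
            read_refmac_external(path)
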