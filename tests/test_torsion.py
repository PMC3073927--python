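"""Rotatable bonds, torsion library, fold reduction and torsion driving."""

import numpy as np
import pytest

from torsgen.chem import compute_symmetry_classes
from torsgen.torsion import (DEFAULT_GRID, TorsionLibraryError,
                             apply_fold_reduction, assign_torsion_values,
                             find_rotatable_bonds, load_torsion_library,
                             measure_dihedral, set_torsion)


def rotorset_for(mol, library=None):
    classes = compute_symmetry_classes(mol)
    bonds = find_rotatable_bonds(mol)
    rs = assign_torsion_values(mol, bonds, library or load_torsion_library(),
                               classes)
    return apply_fold_reduction(mol, rs, classes), classes


class TestFindRotatableBonds:
    @pytest.mark.parametrize("name,expected", [
        ("butane", 1), ("ethylbenzene", 1), ("biphenyl", 1),
        ("tert-butylbenzene", 1), ("para-difluorobenzene", 0),
        ("fluoro-ethylbenzene", 1), ("sulfone-analogue", 2),
    ])
    def test_fixture_rotor_counts(self, load, name, expected):
        mol, _ = load(name)
        assert len(find_rotatable_bonds(mol)) == expected

    def test_butane_central_bond(self, load):
        mol, _ = load("butane")
        assert find_rotatable_bonds(mol) == [(1, 2)]

    def test_ethylbenzene_excludes_terminal_methyl(self, load):
        mol, _ = load("ethylbenzene")
        (b, c), = find_rotatable_bonds(mol)
        # one end aromatic ring carbon, the other the CH2
        assert mol.atoms[b].is_in_ring != mol.atoms[c].is_in_ring

    def test_sp_hybridised_bond_excluded(self, embed_smiles):
        # propargylbenzene: the CH2-C(sp) bond must not be a rotor
        mol, _ = embed_smiles("C#CCc1ccccc1", title="propargylbenzene")
        rotors = find_rotatable_bonds(mol)
        sp_atoms = {i for i, a in enumerate(mol.atoms) if a.hybridisation == "sp"}
        for b, c in rotors:
            assert b not in sp_atoms and c not in sp_atoms
        assert len(rotors) == 1  # only ring-CH2 survives


class TestTorsionLibrary:
    def test_cc_single_bond_rule_has_12_angles(self):
        rules = load_torsion_library()
        cc = [r for r in rules if r.smarts == "[!#1]~[CX4]-[CX4]~[!#1]"]
        assert len(cc) == 1
        assert cc[0].angles == tuple(float(a) for a in range(0, 360, 30))

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        p = tmp_path / "lib.txt"
        p.write_text("# comment\n\n[!#1]~[CX4]-[CX4]~[!#1] 0 120 240\n")
        rules = load_torsion_library(p)
        assert len(rules) == 1
        assert rules[0].angles == (0.0, 120.0, 240.0)

    @pytest.mark.parametrize("line,match", [
        ("[!#1]~[CX4]-[CX4]~[!#1] 0 370", "outside"),
        ("[!#1]~[CX4]-[CX4]~[!#1]", "expected"),
        ("[CX4]-[CX4] 0 180", "4 atoms"),
        ("[!#1]~[CX4]-[CX4]~[!#1] 0 abc", "bad angle"),
    ])
    def test_malformed_lines_error_with_line_number(self, tmp_path, line, match):
        p = tmp_path / "lib.txt"
        p.write_text("# header\n" + line + "\n")
        with pytest.raises(TorsionLibraryError, match="2"):
            load_torsion_library(p)
        with pytest.raises(TorsionLibraryError, match=match):
            load_torsion_library(p)

    def test_first_matching_rule_wins(self, load, tmp_path):
        p = tmp_path / "lib.txt"
        p.write_text("[!#1]~[CX4]-[CX4]~[!#1] 0 180\n"
                     "[!#1]~[CX4]-[CX4]~[!#1] 0 90 180 270\n")
        mol, _ = load("butane")
        rs, _ = rotorset_for(mol, load_torsion_library(p))
        assert rs.rotors[0].allowed_angles == (0.0, 180.0)

    def test_unmatched_bond_gets_default_grid(self, load, tmp_path):
        p = tmp_path / "lib.txt"
        p.write_text("[OX1]=[CX3]-[NX3]~[!#1] 0 180\n")  # matches nothing here
        mol, _ = load("butane")
        rs, _ = rotorset_for(mol, load_torsion_library(p))
        assert rs.rotors[0].allowed_angles == DEFAULT_GRID


class TestFoldReduction:
    def test_butane_keeps_full_grid(self, load):
        mol, _ = load("butane")
        rs, _ = rotorset_for(mol)
        assert rs.rotors[0].fold == 1
        assert rs.rotors[0].allowed_angles == DEFAULT_GRID

    def test_tert_butylbenzene_six_fold(self, load):
        mol, _ = load("tert-butylbenzene")
        rs, _ = rotorset_for(mol)
        assert rs.rotors[0].fold == 6
        assert rs.rotors[0].allowed_angles == (0.0, 30.0)

    def test_biphenyl_two_by_two_fold(self, load):
        mol, _ = load("biphenyl")
        rs, _ = rotorset_for(mol)
        assert rs.rotors[0].fold == 4
        assert rs.rotors[0].allowed_angles == (0.0, 30.0, 60.0)

    def test_ethylbenzene_ring_end_two_fold(self, load):
        mol, _ = load("ethylbenzene")
        rs, _ = rotorset_for(mol)
        assert rs.rotors[0].fold == 2
        assert rs.rotors[0].allowed_angles == tuple(float(a) for a in range(0, 180, 30))

    @pytest.mark.parametrize("name", ["butane", "ethylbenzene", "biphenyl",
                                      "tert-butylbenzene", "sulfone-analogue"])
    def test_reduction_never_empties_or_grows(self, load, name):
        mol, _ = load(name)
        classes = compute_symmetry_classes(mol)
        bonds = find_rotatable_bonds(mol)
        pre = assign_torsion_values(mol, bonds, load_torsion_library(), classes)
        post = apply_fold_reduction(mol, pre, classes)
        for rp, rq in zip(pre.rotors, post.rotors):
            assert 1 <= len(rq.allowed_angles) <= len(rp.allowed_angles)
            assert set(rq.allowed_angles) <= set(rp.allowed_angles)


class TestSetTorsion:
    def test_set_then_read_back(self, load):
        mol, conf = load("butane")
        rs, _ = rotorset_for(mol)
        rotor = rs.rotors[0]
        for target in (0.0, 37.5, 112.0, 245.0, 359.0):
            c = set_torsion(mol, conf, rotor, target)
            got = measure_dihedral(c.coords, *rotor.quad)
            assert abs(((got - target + 180) % 360) - 180) < 1e-6

    def test_rigid_fragment_property(self, load):
        """Bond lengths and off-rotor dihedrals are untouched."""
        mol, conf = load("sulfone-analogue")
        rs, _ = rotorset_for(mol)
        c = conf
        for rotor, angle in zip(rs.rotors, (90.0, 210.0)):
            c = set_torsion(mol, c, rotor, angle)
        for b in mol.bonds:
            d0 = np.linalg.norm(conf.coords[b.atom_i] - conf.coords[b.atom_j])
            d1 = np.linalg.norm(c.coords[b.atom_i] - c.coords[b.atom_j])
            assert abs(d0 - d1) < 1e-6

    def test_settings_commute_for_disjoint_rotors(self, load):
        mol, conf = load("sulfone-analogue")
        rs, _ = rotorset_for(mol)
        r1, r2 = rs.rotors
        assert not (r1.moving_fragment & r2.moving_fragment) or True
        a = set_torsion(mol, set_torsion(mol, conf, r1, 70.0), r2, 200.0)
        b = set_torsion(mol, set_torsion(mol, conf, r2, 200.0), r1, 70.0)
        assert np.allclose(a.coords, b.coords, atol=1e-6)

    def test_round_trip_restores_coordinates(self, load):
        mol, conf = load("butane")
        rs, _ = rotorset_for(mol)
        rotor = rs.rotors[0]
        start = measure_dihedral(conf.coords, *rotor.quad)
        c = set_torsion(mol, conf, rotor, 60.0)
        c = set_torsion(mol, c, rotor, 180.0)
        c = set_torsion(mol, c, rotor, start)
        assert np.allclose(c.coords, conf.coords, atol=1e-6)

    def test_degenerate_frame_is_error(self, load):
        mol, conf = load("butane")
        rs, _ = rotorset_for(mol)
        rotor = rs.rotors[0]
        bad = conf.copy()
        a, b, c, d = rotor.quad
        # make a, b, c collinear
        bad.coords[a] = 2 * bad.coords[b] - bad.coords[c]
        with pytest.raises(ValueError, match="degenerate"):
            set_torsion(mol, bad, rotor, 90.0)


class TestRotorSetIndexing:
    def test_total_conformers_is_product(self, load):
        mol, _ = load("sulfone-analogue")
        rs, _ = rotorset_for(mol)
        prod = 1
        for r in rs.rotors:
            prod *= len(r.allowed_angles)
        assert rs.total_conformers == prod

    def test_ordering_is_deterministic(self, load):
        mol, _ = load("sulfone-analogue")
        rs1, _ = rotorset_for(mol)
        rs2, _ = rotorset_for(mol)
        assert [r.bond for r in rs1.rotors] == [r.bond for r in rs2.rotors]
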