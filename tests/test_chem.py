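"""Molecule I/O, perception, symmetry classes and automorphisms."""

from pathlib import Path

import numpy as np
import pytest
from rdkit import Chem

import torsgen as tg
from torsgen.chem import MoleculeReadError

from conftest import ALL_FIXTURES, brute_force_automorphisms

DATA = Path(__file__).parent / "data"


class TestReadMolecules:
    def test_butane_fixture_counts(self, load):
        mol, conf = load("butane")
        assert mol.n_atoms == 14
        assert mol.n_heavy == 4
        assert conf.coords.shape == (14, 3)
        assert mol.title == "butane"

    def test_multi_record_sdf(self, tmp_path):
        text = "".join(tg.make_fixture(n)
                       for n in ("butane", "ethylbenzene", "biphenyl"))
        p = tmp_path / "three.sdf"
        p.write_text(text)
        records = tg.read_molecules(p)
        assert len(records) == 3
        assert [m.title for m, _ in records] == ["butane", "ethylbenzene", "biphenyl"]

    def test_mol2_reader(self, load):
        records = tg.read_molecules(DATA / "butane.mol2")
        assert len(records) == 1
        mol2_mol, mol2_conf = records[0]
        assert mol2_mol.n_atoms == 14
        sdf_mol, sdf_conf = load("butane")
        assert tg.aligned_rmsd(mol2_conf.coords, sdf_conf.coords,
                               mol2_mol.heavy_atom_indices) < 1e-3

    def test_all_zero_coordinates_rejected(self):
        rd = Chem.AddHs(Chem.MolFromSmiles("CC"))
        conf = Chem.Conformer(rd.GetNumAtoms())  # all positions default to 0
        rd.AddConformer(conf)
        text = Chem.MolToMolBlock(rd) + "$$$$\n"
        with pytest.raises(MoleculeReadError, match="3D"):
            tg.molecules_from_sdf_text(text)

    def test_unparsable_record_names_record_number(self, tmp_path):
        good = tg.make_fixture("butane")
        corrupt = good.replace(" 14 13", " 99 13")  # broken counts line
        text = good + corrupt
        p = tmp_path / "bad.sdf"
        p.write_text(text)
        with pytest.raises(MoleculeReadError, match="record 2"):
            tg.read_molecules(p)

    @pytest.mark.parametrize("name", ALL_FIXTURES)
    def test_perception_invariants(self, load, name):
        mol, _ = load(name)
        heavy = [i for i, a in enumerate(mol.atoms) if a.element != "H"]
        assert mol.heavy_atom_indices == heavy
        for b in mol.bonds:
            assert 0 <= b.atom_i < mol.n_atoms
            assert 0 <= b.atom_j < mol.n_atoms
            assert b.atom_i != b.atom_j


class TestWriteConformers:
    def test_round_trip(self, load, tmp_path):
        mol, conf = load("butane")
        ensemble = []
        rng = np.random.default_rng(3)
        for i in range(5):
            c = conf.copy()
            c.coords = c.coords + rng.normal(scale=0.1, size=c.coords.shape)
            c.rel_energy = float(i) * 1.5
            ensemble.append(c)
        out = tmp_path / "out.sdf"
        tg.write_conformers(out, mol, ensemble)
        back = tg.read_molecules(out)
        assert len(back) == 5
        for (bmol, bconf), orig in zip(back, ensemble):
            # SDF stores 4 decimals
            assert np.allclose(bconf.coords, orig.coords, atol=5e-4)
            assert [a.element for a in bmol.atoms] == [a.element for a in mol.atoms]
            assert sorted((b.atom_i, b.atom_j, b.order) for b in bmol.bonds) == \
                   sorted((b.atom_i, b.atom_j, b.order) for b in mol.bonds)

    def test_energy_tag_and_title(self, load, tmp_path):
        mol, conf = load("butane")
        conf.rel_energy = 1.23456
        out = tmp_path / "one.sdf"
        tg.write_conformers(out, mol, [conf])
        text = out.read_text()
        assert "Energy_rel_kcalmol" in text
        assert "1.2346" in text
        assert "butane conf 1" in text

    def test_empty_ensemble_is_error(self, load, tmp_path):
        mol, _ = load("butane")
        with pytest.raises(ValueError, match="empty"):
            tg.write_conformers(tmp_path / "x.sdf", mol, [])


class TestSymmetryClasses:
    def test_butane_classes(self, load):
        mol, _ = load("butane")
        ids = tg.compute_symmetry_classes(mol).class_ids
        # heavy order C1 C2 C3 C4: terminal pair and central pair
        assert ids[0] == ids[3]
        assert ids[1] == ids[2]
        assert ids[0] != ids[1]

    def test_tert_butylbenzene_methyls_share_class(self, load):
        mol, _ = load("tert-butylbenzene")
        by_atom = tg.compute_symmetry_classes(mol).by_atom(mol)
        # the three methyl carbons: heavy atoms bonded to exactly one heavy atom
        methyls = [i for i in mol.heavy_atom_indices
                   if len(mol.heavy_neighbours(i)) == 1]
        assert len(methyls) == 3
        assert len({by_atom[i] for i in methyls}) == 1

    def test_para_difluorobenzene_ring_carbon_classes(self, load):
        """Ring carbons split into exactly the F-bearing and H-bearing
        orbits of the brute-force automorphism group."""
        mol, _ = load("para-difluorobenzene")
        ids = tg.compute_symmetry_classes(mol).class_ids
        ring_pos = [p for p, a in enumerate(mol.heavy_atom_indices)
                    if mol.atoms[a].element == "C"]
        assert len({ids[p] for p in ring_pos}) == 2
        # orbit oracle: same-orbit atoms must share a class here
        perms = brute_force_automorphisms(mol)
        for perm in perms:
            for p in ring_pos:
                assert ids[p] == ids[perm[p]]

    @pytest.mark.parametrize("name", ALL_FIXTURES)
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_classes_invariant_under_relabelling(self, load, name, seed):
        mol, _ = load(name)
        ids = tg.compute_symmetry_classes(mol).class_ids
        rng = np.random.default_rng(seed)
        order = rng.permutation(mol.n_atoms).tolist()
        rd = Chem.RenumberAtoms(mol.rdmol, order)
        Chem.SanitizeMol(rd)
        mol2, _ = tg.molecules_from_sdf_text(Chem.MolToMolBlock(rd) + "$$$$\n")[0]
        ids2 = tg.compute_symmetry_classes(mol2).class_ids
        assert sorted(ids) == sorted(ids2)


class TestAutomorphisms:
    @pytest.mark.parametrize("name,count", [
        ("butane", 2),                 # path of 4: identity + reversal
        ("para-difluorobenzene", 4),
        ("ethylbenzene", 2),
    ])
    def test_counts_match_brute_force(self, load, name, count):
        mol, _ = load(name)
        autos = tg.enumerate_automorphisms(mol, cap=5000)
        assert not autos.truncated
        assert len(autos) == count
        assert sorted(autos.perms) == brute_force_automorphisms(mol)

    def test_benzene_dihedral_group(self, embed_smiles):
        mol, _ = embed_smiles("c1ccccc1", title="benzene")
        autos = tg.enumerate_automorphisms(mol)
        assert len(autos) == 12

    def test_identity_first_and_permutation_validity(self, load):
        mol, _ = load("biphenyl")
        autos = tg.enumerate_automorphisms(mol)
        n = mol.n_heavy
        assert autos.perms[0] == tuple(range(n))
        for p in autos.perms:
            assert sorted(p) == list(range(n))

    def test_cap_truncates(self, load):
        mol, _ = load("biphenyl")
        autos = tg.enumerate_automorphisms(mol, cap=2)
        assert autos.truncated
        assert len(autos) <= 3  # cap + possibly re-inserted identity
        assert autos.perms[0] == tuple(range(mol.n_heavy))
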