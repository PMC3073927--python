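"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

import torsgen as tg

ROTOR_FIXTURES = ("butane", "ethylbenzene", "tert-butylbenzene", "biphenyl",
                  "fluoro-ethylbenzene", "sulfone-analogue")
ALL_FIXTURES = ROTOR_FIXTURES + ("para-difluorobenzene",)


@pytest.fixture(scope="session")
def load():
    """Session-cached fixture loader returning (MoleculeGraph, fresh conformer)."""
    cache = {}

    def _load(name):
        if name not in cache:
            cache[name] = tg.load_fixture(name)
        mol, conf = cache[name]
        return mol, conf.copy()

    return _load


@pytest.fixture()
def embed_smiles():
    """Build a perceived molecule from SMILES with a deterministic 3D embed."""

    def _embed(smiles, seed=1234, title="mol"):
        rd = Chem.AddHs(Chem.MolFromSmiles(smiles))
        assert AllChem.EmbedMolecule(rd, randomSeed=seed) == 0
        rd.SetProp("_Name", title)
        block = Chem.MolToMolBlock(rd)
        return tg.molecules_from_sdf_text(block + "$$$$\n")[0]

    return _embed


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_automorphisms(mol):
    """All heavy-graph automorphisms by exhaustive permutation search,
    restricted to element-preserving permutations."""
    g = mol.heavy_graph()
    n = g.number_of_nodes()
    key = {i: (g.nodes[i]["element"], g.nodes[i]["charge"]) for i in g.nodes}
    groups = {}
    for i in range(n):
        groups.setdefault(key[i], []).append(i)
    edges = {frozenset(e): g.edges[e]["order"] for e in g.edges}
    perms = []
    group_items = list(groups.values())
    for parts in itertools.product(*(itertools.permutations(grp) for grp in group_items)):
        mapping = {}
        for grp, perm in zip(group_items, parts):
            mapping.update(dict(zip(grp, perm)))
        ok = True
        for (i, j), order in ((tuple(e), o) for e, o in edges.items()):
            if edges.get(frozenset((mapping[i], mapping[j]))) != order:
                ok = False
                break
        if ok:
            perms.append(tuple(mapping[i] for i in range(n)))
    return sorted(perms)


def greedy_filter_from_matrix(records, dist, d):
    """Energy-ordered greedy diversity filter driven by a precomputed
    full pairwise distance matrix (independent of robust_prune)."""
    order = sorted(range(len(records)),
                   key=lambda i: (records[i].rel_energy, records[i].index))
    kept = []
    for i in order:
        if all(dist[i, j] >= d for j in kept):
            kept.append(i)
    return kept


def random_rigid_motion(rng, coords):
    """Apply a uniformly random proper rotation and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.normal(scale=3.0, size=3)
    return coords @ R.T + t


def synthetic_ensemble(rng, base_coords, n, jitter=0.02, spread=0.6,
                       dup_fraction=0.4):
    """An ensemble of conformer records with planted near-duplicates.

    Distinct members are broad perturbations of the base geometry;
    duplicates are rigid motions of an existing member plus a small
    jitter, so they sit within any diversity cutoff well above ~0.1 A.
    """
    members = []
    for i in range(n):
        if members and rng.random() < dup_fraction:
            src = members[rng.integers(len(members))]
            coords = random_rigid_motion(rng, src) + rng.normal(
                scale=jitter, size=src.shape)
        else:
            coords = base_coords + rng.normal(scale=spread, size=base_coords.shape)
        members.append(coords)
    return [tg.ConformerRecord(c, rel_energy=float(rng.normal(5.0, 2.0)), index=i)
            for i, c in enumerate(members)]


def brute_force_grid_pipeline(mol, conf0, rotorset, ctx, autos, d, e_cutoff):
    """Reference generation pipeline: enumerate every grid point in
    ascending index order, apply the energy window against the global
    grid minimum, then the exact energy-ordered greedy diversity filter."""
    from torsgen.search import decode_index
    from torsgen.torsion import set_torsion

    records = []
    for index in range(rotorset.total_conformers):
        conf = conf0
        for rotor, angle in zip(rotorset.rotors, decode_index(index, rotorset)):
            conf = set_torsion(mol, conf, rotor, angle)
        conf.index = index
        conf.rel_energy = tg.total_energy(ctx, conf)
        records.append(conf)
    e_min = min(c.rel_energy for c in records)
    window = []
    for c in records:
        c.rel_energy -= e_min
        if e_cutoff is None or c.rel_energy <= e_cutoff:
            window.append(c)
    kept = []
    for c in sorted(window, key=lambda c: (c.rel_energy, c.index)):
        if all(tg.symmetry_corrected_rmsd(mol, c, k, autos).rmsd >= d
               for k in kept):
            kept.append(c)
    return kept
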