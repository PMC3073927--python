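"""Rotatable bonds, allowed torsion angles and rigid torsion driving.

A rotatable bond is an acyclic single bond whose two atoms are each
connected to at least two non-hydrogen atoms (the bond partner counts)
and neither of which is sp-hybridised.  Allowed dihedral values come
from a plain-text SMARTS torsion library (first matching rule wins, in
file order); bonds no rule matches fall back to a 12-point 30-degree
grid.  Local graph symmetry then shrinks each rotor's angle set:
2-fold at an sp2 carbon whose two rotation-affected heavy neighbours
share a symmetry class, 3-fold at an sp3 carbon with three same-class
heavy neighbours; folds at both bond ends multiply, and the surviving
angles are those below 360/fold degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .chem import ConformerRecord, MoleculeGraph, SymmetryClasses

__all__ = [
    "TorsionRule",
    "Rotor",
    "RotorSet",
    "TorsionLibraryError",
    "DEFAULT_GRID",
    "find_rotatable_bonds",
    "load_torsion_library",
    "default_torsion_library",
    "assign_torsion_values",
    "apply_fold_reduction",
    "measure_dihedral",
    "set_torsion",
]

DEFAULT_GRID: tuple[float, ...] = tuple(float(a) for a in range(0, 360, 30))


class TorsionLibraryError(ValueError):
    """Malformed torsion-library file."""


@dataclass(frozen=True)
class TorsionRule:
    smarts: str
    angles: tuple[float, ...]
    priority: int  # line order; lower wins


@dataclass(frozen=True)
class Rotor:
    """One rotatable bond with its allowed dihedral grid.

    ``quad`` is the reference torsion quadruple (a, b, c, d) of heavy
    atoms used to measure and set the dihedral; ``moving_fragment`` is
    the set of atom indices rotated when the torsion changes (the
    smaller side of the bond, excluding b and c themselves... b/c sit on
    the rotation axis so they never move).
    """

    bond: tuple[int, int]
    quad: tuple[int, int, int, int]
    allowed_angles: tuple[float, ...]
    fold: int
    moving_fragment: frozenset[int]


@dataclass(frozen=True)
class RotorSet:
    """Rotors ordered most-central-first; defines the mixed-radix
    conformer index space (rotor 0 least significant)."""

    rotors: tuple[Rotor, ...]

    @property
    def total_conformers(self) -> int:
        n = 1
        for r in self.rotors:
            n *= len(r.allowed_angles)
        return n

    def __len__(self) -> int:
        return len(self.rotors)


# ---------------------------------------------------------------------------
# rotatable bonds


def find_rotatable_bonds(mol: MoleculeGraph) -> list[tuple[int, int]]:
    """Bonds eligible for torsion driving, as (i, j) atom-index pairs.

    Deterministic order: input bond order, lower atom index first.
    """
    out = []
    for b in mol.bonds:
        if b.is_in_ring or b.order != 1:
            continue
        i, j = sorted((b.atom_i, b.atom_j))
        ai, aj = mol.atoms[i], mol.atoms[j]
        if ai.element == "H" or aj.element == "H":
            continue
        if ai.hybridisation == "sp" or aj.hybridisation == "sp":
            continue
        if len(mol.heavy_neighbours(i)) < 2 or len(mol.heavy_neighbours(j)) < 2:
            continue
        out.append((i, j))
    return out


# ---------------------------------------------------------------------------
# torsion library


def _parse_library(text: str, source: str) -> list[TorsionRule]:
    from rdkit import Chem

    rules = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise TorsionLibraryError(
                f"{source}:{lineno}: expected 'SMARTS angle...'")
        smarts = parts[0]
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise TorsionLibraryError(f"{source}:{lineno}: invalid SMARTS {smarts!r}")
        if patt.GetNumAtoms() != 4:
            raise TorsionLibraryError(
                f"{source}:{lineno}: SMARTS must describe exactly 4 atoms, "
                f"got {patt.GetNumAtoms()}")
        angles = []
        for tok in parts[1:]:
            try:
                a = float(tok)
            except ValueError as exc:
                raise TorsionLibraryError(
                    f"{source}:{lineno}: bad angle {tok!r}") from exc
            if not 0.0 <= a < 360.0:
                raise TorsionLibraryError(
                    f"{source}:{lineno}: angle {a} outside [0, 360)")
            angles.append(a)
        angles = tuple(sorted(set(angles)))
        rules.append(TorsionRule(smarts=smarts, angles=angles, priority=lineno))
    return rules


def load_torsion_library(path: str | Path | None = None) -> list[TorsionRule]:
    """Load a torsion library; with no path, the bundled default library."""
    if path is None:
        return default_torsion_library()
    p = Path(path)
    return _parse_library(p.read_text(), str(p))


def default_torsion_library() -> list[TorsionRule]:
    text = resources.files("torsgen.data").joinpath("torlib.txt").read_text()
    return _parse_library(text, "torlib.txt(default)")


# ---------------------------------------------------------------------------
# rotor construction


def _pick_reference(mol: MoleculeGraph, end: int, other: int,
                    class_by_atom: dict[int, int]) -> int:
    """Deterministic reference neighbour: highest symmetry class, then
    lowest atom index."""
    cands = [a for a in mol.heavy_neighbours(end) if a != other]
    if not cands:
        raise ValueError(f"atom {end} has no heavy neighbour besides {other}")
    return max(cands, key=lambda a: (class_by_atom[a], -a))


def _fragment_split(mol: MoleculeGraph, b: int, c: int) -> frozenset[int]:
    """Atoms on the c side of bond b-c (excluding b), by BFS."""
    seen = {b, c}
    stack = [c]
    while stack:
        x = stack.pop()
        for y in mol.neighbours(x):
            if y not in seen:
                seen.add(y)
                stack.append(y)
    seen.discard(b)
    seen.discard(c)
    return frozenset(seen)


def _bond_centrality(mol: MoleculeGraph, bond: tuple[int, int]) -> int:
    """Eccentricity of the bond's nearer atom over the heavy-atom graph;
    smaller means more central."""
    import networkx as nx

    g = mol.heavy_graph()
    pos = {a: i for i, a in enumerate(mol.heavy_atom_indices)}
    ecc = []
    for a in bond:
        dist = nx.single_source_shortest_path_length(g, pos[a])
        ecc.append(max(dist.values()))
    return min(ecc)


def assign_torsion_values(mol: MoleculeGraph, bonds: list[tuple[int, int]],
                          library: list[TorsionRule],
                          classes: SymmetryClasses | None = None) -> RotorSet:
    """Build the pre-reduction rotor set for the given rotatable bonds.

    The first library rule (file order) whose middle two SMARTS atoms map
    onto the bond wins; unmatched bonds get the default 30-degree grid.
    Rotors are ordered most central first (ties by input bond order).
    """
    from rdkit import Chem

    if classes is None:
        from .chem import compute_symmetry_classes

        classes = compute_symmetry_classes(mol)
    class_by_atom = classes.by_atom(mol)

    matches_by_bond: dict[tuple[int, int], tuple[float, ...]] = {}
    for rule in library:
        patt = Chem.MolFromSmarts(rule.smarts)
        for match in mol.rdmol.GetSubstructMatches(patt, uniquify=False):
            key = tuple(sorted((match[1], match[2])))
            matches_by_bond.setdefault(key, rule.angles)

    rotors = []
    for b, c in bonds:
        angles = matches_by_bond.get((b, c), DEFAULT_GRID)
        a = _pick_reference(mol, b, c, class_by_atom)
        d = _pick_reference(mol, c, b, class_by_atom)
        frag_c = _fragment_split(mol, b, c)
        frag_b = _fragment_split(mol, c, b)
        if len(frag_c) < len(frag_b):
            moving = frag_c
        elif len(frag_b) < len(frag_c):
            moving = frag_b
        else:
            moving = frag_c if 0 in frag_b else frag_b
        rotors.append(Rotor(bond=(b, c), quad=(a, b, c, d),
                            allowed_angles=tuple(angles), fold=1,
                            moving_fragment=moving))
    order = sorted(range(len(rotors)),
                   key=lambda i: (_bond_centrality(mol, rotors[i].bond), i))
    return RotorSet(rotors=tuple(rotors[i] for i in order))


def _end_fold(mol: MoleculeGraph, end: int, other: int,
              class_by_atom: dict[int, int]) -> int:
    atom = mol.atoms[end]
    if atom.element != "C":
        return 1
    neigh = [a for a in mol.heavy_neighbours(end) if a != other]
    cls = [class_by_atom[a] for a in neigh]
    if atom.hybridisation == "sp2" and len(cls) == 2 and cls[0] == cls[1]:
        return 2
    if atom.hybridisation == "sp3" and len(cls) == 3 and len(set(cls)) == 1:
        return 3
    return 1


def apply_fold_reduction(mol: MoleculeGraph, rotorset: RotorSet,
                         classes: SymmetryClasses) -> RotorSet:
    """Shrink each rotor's angle set by its topological symmetry fold.

    The folds found at the two bond ends multiply; surviving angles are
    those strictly below 360/fold (with a small tolerance so grid values
    exactly at the boundary are excluded, matching the halving of a
    0/180 pair to {0}).
    """
    class_by_atom = classes.by_atom(mol)
    new_rotors = []
    for r in rotorset.rotors:
        b, c = r.bond
        fold = _end_fold(mol, b, c, class_by_atom) * _end_fold(mol, c, b, class_by_atom)
        if fold == 1:
            new_rotors.append(r)
            continue
        limit = 360.0 / fold
        kept = tuple(a for a in r.allowed_angles if a < limit - 1e-9)
        if not kept:
            # never empty the grid: keep the smallest representative
            kept = (min(r.allowed_angles),)
        new_rotors.append(replace(r, fold=fold, allowed_angles=kept))
    return RotorSet(rotors=tuple(new_rotors))


# ---------------------------------------------------------------------------
# torsion driving


def measure_dihedral(coords: np.ndarray, a: int, b: int, c: int, d: int) -> float:
    """Signed dihedral a-b-c-d mapped to [0, 360) degrees."""
    p = coords
    b0 = p[b] - p[a]
    b1 = p[c] - p[b]
    b2 = p[d] - p[c]
    c01 = np.cross(b0, b1)
    c12 = np.cross(b1, b2)
    n1 = np.linalg.norm(c01)
    n2 = np.linalg.norm(c12)
    if n1 < 1e-10 or n2 < 1e-10:
        raise ValueError("degenerate torsion frame")
    x = float(np.dot(c01, c12))
    y = float(np.dot(np.cross(c01, c12), b1 / np.linalg.norm(b1)))
    ang = math.degrees(math.atan2(y, x))
    return ang % 360.0


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    u = axis / np.linalg.norm(axis)
    ux, uy, uz = u
    c = math.cos(angle_rad)
    s = math.sin(angle_rad)
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def set_torsion(mol: MoleculeGraph, conf: ConformerRecord, rotor: Rotor,
                angle_deg: float) -> ConformerRecord:
    """Rigidly rotate the rotor's moving fragment about the b-c axis so
    the reference quadruple's dihedral equals ``angle_deg``.

    Bond lengths and angles are untouched; only atoms in
    ``moving_fragment`` move.  Returns a new record (input unchanged).
    """
    if not 0.0 <= angle_deg < 360.0:
        angle_deg = angle_deg % 360.0
    a, b, c, d = rotor.quad
    coords = conf.coords.copy()
    current = measure_dihedral(coords, a, b, c, d)
    delta = math.radians(angle_deg - current)
    if abs(delta) < 1e-15:
        return ConformerRecord(coords, conf.rel_energy, conf.index)
    # rotating the c-side fragment by +delta about the b->c axis
    # increases the a-b-c-d dihedral by +delta; the a-side moves with
    # the opposite sign.
    axis = coords[c] - coords[b]
    sign = 1.0 if c in rotor.moving_fragment or d in rotor.moving_fragment else -1.0
    rot = _rotation_about_axis(axis, sign * delta)
    moving = sorted(rotor.moving_fragment)
    origin = coords[b]
    coords[moving] = (coords[moving] - origin) @ rot.T + origin
    got = measure_dihedral(coords, a, b, c, d)
    err = ((got - angle_deg + 180.0) % 360.0) - 180.0
    if abs(err) > 1e-6:
        # sign convention fallback; exact rigid rotation either way
        rot = _rotation_about_axis(axis, -sign * delta)
        coords = conf.coords.copy()
        coords[moving] = (coords[moving] - origin) @ rot.T + origin
        got = measure_dihedral(coords, a, b, c, d)
        err = ((got - angle_deg + 180.0) % 360.0) - 180.0
        if abs(err) > 1e-6:
            raise RuntimeError(f"torsion drive failed: target {angle_deg}, got {got}")
    return ConformerRecord(coords, conf.rel_energy, conf.index)
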