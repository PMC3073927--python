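"""Molecule and conformer data model, SDF/MOL2 input and output, and
topological-symmetry perception.

The in-memory model is a thin, explicit layer over RDKit: a
:class:`MoleculeGraph` keeps the perceived atom/bond facts the search
needs (hybridisation, ring membership, heavy-atom symmetry classes) and
holds the underlying RDKit molecule for SMARTS matching and MMFF94
evaluation.  Geometries travel separately as :class:`ConformerRecord`
objects so one molecule can carry many conformers cheaply.

Symmetry classes are computed on the heavy-atom graph only: hydrogens
are excluded from every RMSD in this package, so hydrogen-interchange
symmetry never matters downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "AtomInfo",
    "BondInfo",
    "MoleculeGraph",
    "ConformerRecord",
    "SymmetryClasses",
    "AutomorphismSet",
    "MoleculeReadError",
    "read_molecules",
    "molecules_from_sdf_text",
    "write_conformers",
    "compute_symmetry_classes",
    "enumerate_automorphisms",
]

ENERGY_TAG = "Energy_rel_kcalmol"

_HYBRID_MAP = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


class MoleculeReadError(ValueError):
    """Raised when an input record cannot be parsed or lacks 3D coordinates."""


@dataclass(frozen=True)
class AtomInfo:
    element: str
    formal_charge: int
    is_in_ring: bool
    hybridisation: str  # "sp" | "sp2" | "sp3" | "other"


@dataclass(frozen=True)
class BondInfo:
    atom_i: int
    atom_j: int
    order: float  # 1, 2, 3 or 1.5 for aromatic
    is_in_ring: bool


@dataclass
class MoleculeGraph:
    """Perceived molecular graph with 0-based contiguous atom indices."""

    atoms: list[AtomInfo]
    bonds: list[BondInfo]
    title: str
    heavy_atom_indices: list[int]
    rdmol: Chem.Mol = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.atom_i < n and 0 <= b.atom_j < n and b.atom_i != b.atom_j):
                raise ValueError(f"bond {b} references invalid atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_atom_indices)

    def neighbours(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.atom_i == idx:
                out.append(b.atom_j)
            elif b.atom_j == idx:
                out.append(b.atom_i)
        return out

    def heavy_neighbours(self, idx: int) -> list[int]:
        return [j for j in self.neighbours(idx) if self.atoms[j].element != "H"]

    def heavy_graph(self) -> nx.Graph:
        """Heavy-atom graph; nodes are positions in ``heavy_atom_indices``."""
        pos = {a: i for i, a in enumerate(self.heavy_atom_indices)}
        g = nx.Graph()
        for i, a in enumerate(self.heavy_atom_indices):
            info = self.atoms[a]
            g.add_node(i, element=info.element, charge=info.formal_charge)
        for b in self.bonds:
            if b.atom_i in pos and b.atom_j in pos:
                g.add_edge(pos[b.atom_i], pos[b.atom_j], order=b.order)
        return g


@dataclass
class ConformerRecord:
    """One geometry of a molecule, in Angstroms.

    ``rel_energy`` is kcal/mol relative to the current energy reference
    (the lowest-energy conformer known so far); it is only guaranteed
    non-negative once the final reference has been fixed at the end of a
    search.  ``index`` is the mixed-radix conformer index within the
    torsion grid (0 for input structures).
    """

    coords: np.ndarray
    rel_energy: float = 0.0
    index: int = 0

    def copy(self) -> "ConformerRecord":
        return ConformerRecord(self.coords.copy(), self.rel_energy, self.index)


@dataclass
class SymmetryClasses:
    """Canonical topological equivalence classes of the heavy atoms.

    ``class_ids[i]`` is the class of the i-th heavy atom (position in
    ``heavy_atom_indices``).  Ids are ranks of relabelling-invariant
    refinement keys, so isomorphic inputs get identical ids.
    """

    class_ids: list[int]

    def by_atom(self, mol: MoleculeGraph) -> dict[int, int]:
        return {a: c for a, c in zip(mol.heavy_atom_indices, self.class_ids)}


@dataclass
class AutomorphismSet:
    """Automorphisms of the heavy-atom graph, as permutations of heavy
    positions: ``perm[i] = j`` maps heavy position i onto heavy position j."""

    perms: list[tuple[int, ...]]
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.perms)


# ---------------------------------------------------------------------------
# reading / writing


def _from_rdkit(mol: Chem.Mol, record_no: int) -> tuple[MoleculeGraph, ConformerRecord]:
    if mol.GetNumConformers() == 0:
        raise MoleculeReadError(f"record {record_no}: no coordinates; input must be 3D")
    coords = mol.GetConformer().GetPositions().astype(float)
    if np.allclose(coords, 0.0):
        raise MoleculeReadError(f"record {record_no}: all-zero coordinates; input must be 3D")
    Chem.AssignStereochemistryFrom3D(mol)
    atoms = []
    for a in mol.GetAtoms():
        atoms.append(
            AtomInfo(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                is_in_ring=a.IsInRing(),
                hybridisation=_HYBRID_MAP.get(a.GetHybridization(), "other"),
            )
        )
    bonds = []
    for b in mol.GetBonds():
        if b.GetIsAromatic():
            order = 1.5
        else:
            order = float(int(b.GetBondTypeAsDouble()))
        bonds.append(BondInfo(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, b.IsInRing()))
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() != "H"]
    title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    graph = MoleculeGraph(atoms=atoms, bonds=bonds, title=title,
                          heavy_atom_indices=heavy, rdmol=mol)
    return graph, ConformerRecord(coords=coords)


def molecules_from_sdf_text(text: str) -> list[tuple[MoleculeGraph, ConformerRecord]]:
    """Parse a multi-record SDF string (hydrogens retained)."""
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, removeHs=False, sanitize=True)
    out = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise MoleculeReadError(f"record {i + 1}: unparsable SDF record")
        out.append(_from_rdkit(mol, i + 1))
    if not out:
        raise MoleculeReadError("no records found in SDF input")
    return out


def _split_mol2(text: str) -> list[str]:
    marker = "@<TRIPOS>MOLECULE"
    parts = text.split(marker)
    return [marker + p for p in parts[1:]]


def read_molecules(path: str | Path, fmt: str | None = None
                   ) -> list[tuple[MoleculeGraph, ConformerRecord]]:
    """Read a (multi-record) SDF or MOL2 file into perceived molecules.

    Hydrogens are retained; hybridisation and ring flags are perceived on
    read.  Records that fail to parse raise :class:`MoleculeReadError`
    naming the record number, as do 2D / all-zero-coordinate inputs.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"sdf": "sdf", "sd": "sdf", "mol": "sdf", "mol2": "mol2"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from extension {path.suffix!r}")
    fmt = fmt.lower()
    text = path.read_text()
    if fmt == "sdf":
        return molecules_from_sdf_text(text)
    if fmt == "mol2":
        out = []
        for i, block in enumerate(_split_mol2(text)):
            mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=True)
            if mol is None:
                raise MoleculeReadError(f"record {i + 1}: unparsable MOL2 record")
            out.append(_from_rdkit(mol, i + 1))
        if not out:
            raise MoleculeReadError("no records found in MOL2 input")
        return out
    raise ValueError(f"unsupported format {fmt!r}")


def write_conformers(path: str | Path, mol: MoleculeGraph,
                     ensemble: Sequence[ConformerRecord]) -> None:
    """Write an ensemble as a multi-record SDF.

    Each record carries the relative energy (kcal/mol, 4 decimals) in the
    ``Energy_rel_kcalmol`` SD tag and the molecule title with a conformer
    ordinal suffix.
    """
    if not ensemble:
        raise ValueError("cannot write an empty ensemble")
    path = Path(path)
    rd = Chem.Mol(mol.rdmol)
    writer = Chem.SDWriter(str(path))
    try:
        for i, conf in enumerate(ensemble):
            if conf.coords.shape != (mol.n_atoms, 3):
                raise ValueError("conformer coordinate shape does not match molecule")
            c = rd.GetConformer()
            for j in range(mol.n_atoms):
                c.SetAtomPosition(j, conf.coords[j].tolist())
            rd.SetProp("_Name", f"{mol.title} conf {i + 1}".strip())
            rd.SetProp(ENERGY_TAG, f"{conf.rel_energy:.4f}")
            writer.write(rd)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# topological symmetry


def compute_symmetry_classes(mol: MoleculeGraph) -> SymmetryClasses:
    """Iterative-refinement (Morgan-style) partition of the heavy atoms.

    Seeds each heavy atom with (element, heavy degree, formal charge, ring
    membership, sum of heavy-bond orders) and refines with the sorted
    multiset of neighbour classes until a fixed point.  Class ids are
    ranks of the refinement keys, hence invariant under atom relabelling.
    """
    if mol.n_heavy < 1:
        raise ValueError("molecule has no heavy atoms")
    g = mol.heavy_graph()
    keys: dict[int, tuple] = {}
    for i in g.nodes:
        orders = sorted(g.edges[i, j]["order"] for j in g.neighbors(i))
        d = g.nodes[i]
        keys[i] = (d["element"], g.degree[i], d["charge"],
                   mol.atoms[mol.heavy_atom_indices[i]].is_in_ring,
                   tuple(orders))
    n_classes = len(set(keys.values()))
    while True:
        new_keys = {
            i: (keys[i], tuple(sorted(keys[j] for j in g.neighbors(i))))
            for i in g.nodes
        }
        n_new = len(set(new_keys.values()))
        if n_new == n_classes:
            break
        keys = new_keys
        n_classes = n_new
    ranks = {k: r for r, k in enumerate(sorted(set(keys.values())))}
    return SymmetryClasses(class_ids=[ranks[keys[i]] for i in range(g.number_of_nodes())])


def enumerate_automorphisms(mol: MoleculeGraph, cap: int = 5000) -> AutomorphismSet:
    """All automorphisms of the heavy-atom graph, up to ``cap``.

    Automorphisms preserve element, formal charge and bond order.  When
    the cap is reached the set is truncated (with the identity guaranteed
    present) and downstream symmetry-corrected RMSD degrades gracefully.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    g = mol.heavy_graph()
    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["element", "charge"], ["", 0])
    em = nx.algorithms.isomorphism.categorical_edge_match("order", 0)
    matcher = nx.algorithms.isomorphism.GraphMatcher(g, g, node_match=nm, edge_match=em)
    n = g.number_of_nodes()
    perms: list[tuple[int, ...]] = []
    truncated = False
    for mapping in matcher.isomorphisms_iter():
        perms.append(tuple(mapping[i] for i in range(n)))
        if len(perms) >= cap:
            truncated = True
            break
    identity = tuple(range(n))
    if identity not in perms:
        perms.insert(0, identity)
    else:
        perms.remove(identity)
        perms.insert(0, identity)
    if truncated:
        logger.warning(
            "automorphism enumeration for %r truncated at %d; "
            "symmetry correction may be incomplete", mol.title, cap)
    return AutomorphismSet(perms=perms, truncated=truncated)
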