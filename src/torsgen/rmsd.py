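"""Heavy-atom least-squares RMSD and its symmetry-corrected variant.

The plain RMSD superimposes the heavy-atom subsets by the optimal proper
rotation + translation (Kabsch, with the reflection excluded: mirror
images are distinct conformers).  Topologically equivalent atoms (for
example the two ortho/meta pairs of a para-substituted phenyl ring) can
make the plain RMSD overestimate the true difference between two
conformations; the symmetry-corrected RMSD removes this by minimising
over the graph automorphisms of the molecule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import AutomorphismSet, ConformerRecord, MoleculeGraph

__all__ = ["RmsdResult", "aligned_rmsd", "symmetry_corrected_rmsd"]


@dataclass(frozen=True)
class RmsdResult:
    rmsd: float
    best_automorphism: tuple[int, ...]


def _kabsch_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Minimum RMSD between point sets A, B (N x 3) over proper rigid
    motions of B onto A."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    H = B.T @ A
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    # exclude reflections: flip the smallest singular direction if needed
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    # explicit residual: numerically exact at zero, unlike the trace form
    res = A - B @ R
    return float(np.sqrt(np.mean(np.sum(res * res, axis=1))))


def aligned_rmsd(coordsA: np.ndarray, coordsB: np.ndarray,
                 heavy_idx: Sequence[int]) -> float:
    """Heavy-atom RMSD after optimal proper superposition.

    ``heavy_idx`` selects the rows compared (atom correspondence is
    positional).  Raises ``ValueError`` on mismatched atom counts.
    """
    if coordsA.shape != coordsB.shape:
        raise ValueError(
            f"coordinate shapes differ: {coordsA.shape} vs {coordsB.shape}")
    idx = np.asarray(heavy_idx, dtype=int)
    return _kabsch_rmsd(coordsA[idx], coordsB[idx])


def symmetry_corrected_rmsd(mol: MoleculeGraph, confA: ConformerRecord,
                            confB: ConformerRecord,
                            autos: AutomorphismSet) -> RmsdResult:
    """Minimum heavy-atom RMSD over the molecule's graph automorphisms.

    For each automorphism p, heavy atom i of A is matched with heavy
    atom p[i] of B; the reported result carries the winning permutation.
    Always <= the plain aligned RMSD because the identity is present.
    """
    if not autos.perms:
        raise ValueError("automorphism set must contain at least the identity")
    idx = np.asarray(mol.heavy_atom_indices, dtype=int)
    HA = confA.coords[idx]
    HB = confB.coords[idx]
    best = None
    best_perm = autos.perms[0]
    for perm in autos.perms:
        r = _kabsch_rmsd(HA, HB[np.asarray(perm, dtype=int)])
        if best is None or r < best:
            best = r
            best_perm = perm
    return RmsdResult(rmsd=float(best), best_automorphism=best_perm)
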