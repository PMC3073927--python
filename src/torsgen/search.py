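"""Systematic conformer generation.

The torsion grid of a molecule defines a mixed-radix index space: one
digit per rotor (rotor 0, the most central, is the least significant
digit), each digit running over that rotor's allowed angles.  The space
is traversed in pseudorandom order by a maximal-length linear feedback
shift register (LFSR), which emits every integer in 1..2^k-1 exactly
once with constant memory; values above the grid size are skipped.
Random-order traversal avoids biasing the stored ensemble towards any
one region of torsion space when the conformer cap truncates the search.

Each visited conformer is built by rigid torsion driving from the input
geometry, windowed on energy relative to the best conformer known so
far (the window reference drops whenever a lower energy appears), and
passed through the fast diversity filter.  A final exact, energy-ordered
prune with the symmetry-corrected RMSD fixes both the energy window
(against the final reference) and any near-duplicates the fast filter
let through.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .chem import (AutomorphismSet, ConformerRecord, MoleculeGraph,
                   compute_symmetry_classes, enumerate_automorphisms)
from .diversity import fast_insert, make_tree, robust_prune
from .forcefield import FFContext, setup_forcefield, total_energy, variable_energy
from .rmsd import aligned_rmsd, symmetry_corrected_rmsd
from .torsion import (RotorSet, apply_fold_reduction, assign_torsion_values,
                      find_rotatable_bonds, load_torsion_library, set_torsion)

logger = logging.getLogger(__name__)

__all__ = ["SearchOptions", "SearchStats", "lfsr_sequence", "decode_index",
           "encode_index", "greedy_seed", "generate_conformers", "run_search",
           "build_rotorset"]

# Maximal-length LFSR tap masks per register width (Galois form: mask bit
# t-1 set for each feedback polynomial tap t, including the width itself).
# One published maximal-length polynomial per width 2..32.
_TAPS: dict[int, int] = {
    2: 0x3, 3: 0x6, 4: 0xC, 5: 0x14, 6: 0x30, 7: 0x60, 8: 0xB8,
    9: 0x110, 10: 0x240, 11: 0x500, 12: 0x829, 13: 0x100D, 14: 0x2015,
    15: 0x6000, 16: 0xD008, 17: 0x12000, 18: 0x20400, 19: 0x40023,
    20: 0x90000, 21: 0x140000, 22: 0x300000, 23: 0x420000, 24: 0xE10000,
    25: 0x1200000, 26: 0x2000023, 27: 0x4000013, 28: 0x9000000,
    29: 0x14000000, 30: 0x20000029, 31: 0x48000000, 32: 0x80200003,
}


@dataclass
class SearchOptions:
    """User-facing knobs of the generator.

    diversity_d    RMSD diversity cutoff in Angstroms (required).
    energy_cutoff  window above the lowest-energy conformer, kcal/mol;
                   None disables the window.
    conformer_cap  maximum number of grid conformers tested.
    torlib         path to a torsion library file (None: bundled default).
    """

    diversity_d: float
    energy_cutoff: float | None = 50.0
    conformer_cap: int = 10**6
    torlib: str | None = None
    verbose: bool = False
    automorphism_cap: int = 5000

    def __post_init__(self) -> None:
        if self.diversity_d <= 0:
            raise ValueError("diversity_d must be positive")
        if self.energy_cutoff is not None and self.energy_cutoff <= 0:
            raise ValueError("energy_cutoff must be positive (or None)")
        if self.conformer_cap < 1:
            raise ValueError("conformer_cap must be >= 1")


@dataclass
class SearchStats:
    n_rotors: int = 0
    total_conformers: int = 1
    tested: int = 0
    low_energy: int = 0
    stored: int = 0
    kept: int = 0
    rmsd_evaluations: int = 0


def lfsr_sequence(n: int) -> Iterator[int]:
    """Yield 1..n, each exactly once, in pseudorandom LFSR order.

    The smallest register width k with 2^k - 1 >= n is used; emitted
    values above n are skipped.  Deterministic (seed state 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        yield 1
        return
    k = 2
    while (1 << k) - 1 < n:
        k += 1
    mask = _TAPS[k]
    state = 1
    for _ in range((1 << k) - 1):
        if state <= n:
            yield state
        lsb = state & 1
        state >>= 1
        if lsb:
            state ^= mask


def decode_index(index: int, rotorset: RotorSet) -> list[float]:
    """Mixed-radix decode of a conformer index to one angle per rotor."""
    angles = []
    for rotor in rotorset.rotors:
        base = len(rotor.allowed_angles)
        angles.append(rotor.allowed_angles[index % base])
        index //= base
    if index != 0:
        raise ValueError("index out of range for this rotor set")
    return angles


def encode_index(angles: list[float], rotorset: RotorSet) -> int:
    """Inverse of :func:`decode_index`."""
    index = 0
    for rotor, angle in zip(reversed(rotorset.rotors), reversed(angles)):
        base = len(rotor.allowed_angles)
        digit = rotor.allowed_angles.index(angle)
        index = index * base + digit
    return index


def build_rotorset(mol: MoleculeGraph, torlib: str | None = None) -> RotorSet:
    """Perceive rotors, assign torsion values and apply fold reduction."""
    classes = compute_symmetry_classes(mol)
    bonds = find_rotatable_bonds(mol)
    library = load_torsion_library(torlib)
    rotorset = assign_torsion_values(mol, bonds, library, classes)
    return apply_fold_reduction(mol, rotorset, classes)


def _build_conformer(mol: MoleculeGraph, base: ConformerRecord,
                     rotorset: RotorSet, angles: list[float],
                     index: int) -> ConformerRecord:
    conf = base
    for rotor, angle in zip(rotorset.rotors, angles):
        conf = set_torsion(mol, conf, rotor, angle)
    conf.index = index
    return conf


def greedy_seed(mol: MoleculeGraph, rotorset: RotorSet, ctx: FFContext,
                conf0: ConformerRecord) -> tuple[ConformerRecord, float]:
    """Greedy estimate of the lowest-energy conformer.

    One outward pass sets each rotor (most central first) to its
    variable-energy argmin with the others fixed.  The pass is repeated
    for up to 16 different orderings of the (at most) four most central
    rotors, lexicographically; the best total energy found becomes the
    initial reference for the energy window.
    """
    if len(rotorset) == 0:
        raise ValueError("greedy_seed requires at least one rotor")
    n = len(rotorset)
    m = min(4, n)
    orderings = list(itertools.islice(itertools.permutations(range(m)), 16))
    best_conf = None
    best_energy = math.inf
    for perm in orderings:
        order = list(perm) + list(range(m, n))
        conf = conf0.copy()
        for ri in order:
            rotor = rotorset.rotors[ri]
            best_angle = None
            best_var = math.inf
            for angle in rotor.allowed_angles:
                trial = set_torsion(mol, conf, rotor, angle)
                e = variable_energy(ctx, trial)
                if e < best_var:
                    best_var = e
                    best_angle = angle
            conf = set_torsion(mol, conf, rotor, best_angle)
        e_tot = total_energy(ctx, conf)
        if e_tot < best_energy:
            best_energy = e_tot
            best_conf = conf
    return best_conf, best_energy


def run_search(mol: MoleculeGraph, conf0: ConformerRecord,
               options: SearchOptions) -> tuple[list[ConformerRecord], SearchStats]:
    """Full generation pipeline; returns (ensemble, statistics).

    The ensemble is sorted by relative energy (kcal/mol above the final
    reference), every member is inside the energy window, and all
    pairwise symmetry-corrected heavy-atom RMSDs are >= diversity_d.
    """
    stats = SearchStats()
    ctx = setup_forcefield(mol, conf0)
    rotorset = build_rotorset(mol, options.torlib)
    stats.n_rotors = len(rotorset)
    stats.total_conformers = rotorset.total_conformers
    autos = enumerate_automorphisms(mol, cap=options.automorphism_cap)
    if autos.truncated:
        autos = AutomorphismSet(perms=[autos.perms[0]], truncated=True)

    def rmsd_plain(a: ConformerRecord, b: ConformerRecord) -> float:
        return aligned_rmsd(a.coords, b.coords, mol.heavy_atom_indices)

    def rmsd_sym(a: ConformerRecord, b: ConformerRecord) -> float:
        return symmetry_corrected_rmsd(mol, a, b, autos).rmsd

    if len(rotorset) == 0:
        out = conf0.copy()
        out.rel_energy = 0.0
        stats.tested = stats.low_energy = stats.stored = stats.kept = 1
        return [out], stats

    _, e_ref = greedy_seed(mol, rotorset, ctx, conf0)

    tree = make_tree(options.diversity_d)
    stored_coords: dict[int, np.ndarray] = {}
    window: list[tuple[int, float]] = []  # (index, absolute energy)
    n_total = rotorset.total_conformers
    for value in lfsr_sequence(n_total):
        if stats.tested >= options.conformer_cap:
            break
        index = value - 1
        stats.tested += 1
        angles = decode_index(index, rotorset)
        conf = _build_conformer(mol, conf0, rotorset, angles, index)
        energy = total_energy(ctx, conf)
        if energy < e_ref:
            e_ref = energy  # lower reference used from this point on
        if options.energy_cutoff is not None and energy - e_ref > options.energy_cutoff:
            continue
        window.append((index, energy))
        conf.rel_energy = energy - e_ref
        if fast_insert(tree, conf, rmsd_plain):
            stored_coords[index] = conf.coords
    stats.stored = len(stored_coords)
    stats.rmsd_evaluations = tree.rmsd_evaluations

    # Re-filter the energy window against the final reference (it may
    # have dropped after a conformer was admitted), then run the exact
    # energy-ordered prune over the whole window.  Keeping every
    # window-passing (index, energy) pair — scalars only — and rebuilding
    # discarded geometries on demand makes the final ensemble exactly the
    # greedy optimum over all low-energy grid conformers, independent of
    # the pseudorandom traversal order.
    final: list[ConformerRecord] = []
    for index, energy in window:
        rel = energy - e_ref
        if options.energy_cutoff is not None and rel > options.energy_cutoff:
            continue
        coords = stored_coords.get(index)
        if coords is None:
            coords = _build_conformer(
                mol, conf0, rotorset, decode_index(index, rotorset), index).coords
        final.append(ConformerRecord(coords, rel, index))
    stats.low_energy = len(final)
    kept = robust_prune(final, options.diversity_d, rmsd_sym)
    kept.sort(key=lambda c: (c.rel_energy, c.index))
    stats.kept = len(kept)
    if options.verbose:
        logger.info(
            "molecule=%r rotors=%d total=%d tested=%d low_energy=%d "
            "stored=%d kept=%d", mol.title, stats.n_rotors,
            stats.total_conformers, stats.tested, stats.low_energy,
            stats.stored, stats.kept)
    return kept, stats


def generate_conformers(mol: MoleculeGraph, conf0: ConformerRecord,
                        options: SearchOptions) -> list[ConformerRecord]:
    """The diverse low-energy ensemble for one molecule (see
    :func:`run_search` for the statistics-bearing variant)."""
    ensemble, _ = run_search(mol, conf0, options)
    return ensemble
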