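"""Crystal-structure recovery benchmarking.

Given generated ensembles and reference (crystal) conformations of the
same molecules, this module computes each molecule's minimum
symmetry-corrected heavy-atom RMSD to its reference and aggregates the
standard percent-recovery metric: the fraction of molecules with at
least one generated conformer within a cutoff (commonly 1.0, 1.5 and
2.0 A) of the crystal structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .chem import (AutomorphismSet, ConformerRecord, MoleculeGraph,
                   enumerate_automorphisms)
from .rmsd import symmetry_corrected_rmsd

logger = logging.getLogger(__name__)

__all__ = ["MoleculeReport", "RecoveryReport", "min_rmsd_to_reference",
           "percent_recovery", "ensemble_statistics", "pair_molecules",
           "DEFAULT_CUTOFFS"]

DEFAULT_CUTOFFS = (1.0, 1.5, 2.0)


@dataclass
class MoleculeReport:
    title: str
    n_rotors: int
    min_rmsd: float
    total_conformers: int = 0
    tested: int = 0
    low_energy: int = 0
    diverse: int = 0


@dataclass
class RecoveryReport:
    """Per-molecule minimum RMSDs plus aggregate recovery."""

    molecules: list[MoleculeReport] = field(default_factory=list)

    def recovery_at(self, cutoff: float) -> float:
        return percent_recovery([m.min_rmsd for m in self.molecules], cutoff)

    def summary(self, cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS) -> dict[float, float]:
        return {c: self.recovery_at(c) for c in cutoffs}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"title": m.title, "n_rotors": m.n_rotors, "min_rmsd": m.min_rmsd,
              "total_conformers": m.total_conformers, "tested": m.tested,
              "low_energy": m.low_energy, "diverse": m.diverse}
             for m in self.molecules])


def _same_heavy_graph(a: MoleculeGraph, b: MoleculeGraph) -> bool:
    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["element", "charge"], ["", 0])
    em = nx.algorithms.isomorphism.categorical_edge_match("order", 0)
    return nx.is_isomorphic(a.heavy_graph(), b.heavy_graph(),
                            node_match=nm, edge_match=em)


def min_rmsd_to_reference(mol: MoleculeGraph, ensemble: list[ConformerRecord],
                          reference_conf: ConformerRecord,
                          reference_mol: MoleculeGraph | None = None,
                          autos: AutomorphismSet | None = None) -> float:
    """Minimum symmetry-corrected RMSD from any ensemble member to the
    reference conformation.

    When the reference comes from a separate file, pass its perceived
    graph as ``reference_mol``; a heavy-graph mismatch is an error.
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    if reference_mol is not None and not _same_heavy_graph(mol, reference_mol):
        raise ValueError(
            f"reference molecule {reference_mol.title!r} does not match "
            f"{mol.title!r} (different heavy-atom graphs)")
    if autos is None:
        autos = enumerate_automorphisms(mol)
    return min(symmetry_corrected_rmsd(mol, conf, reference_conf, autos).rmsd
               for conf in ensemble)


def percent_recovery(min_rmsds: list[float], cutoff: float) -> float:
    """100 x fraction of molecules whose minimum RMSD is <= cutoff."""
    if not min_rmsds:
        raise ValueError("no molecules to evaluate")
    hits = sum(1 for r in min_rmsds if r <= cutoff)
    return 100.0 * hits / len(min_rmsds)


def ensemble_statistics(report: RecoveryReport) -> pd.DataFrame:
    """Median conformer counts and minimum RMSD grouped by rotor count."""
    df = report.to_frame()
    if df.empty:
        raise ValueError("report contains no molecules")
    grouped = df.groupby("n_rotors").agg(
        n_molecules=("title", "size"),
        total_conformers=("total_conformers", "median"),
        low_energy=("low_energy", "median"),
        diverse=("diverse", "median"),
        min_rmsd=("min_rmsd", "median"),
    )
    return grouped.reset_index()


def pair_molecules(generated: list[tuple[MoleculeGraph, list[ConformerRecord]]],
                   references: list[tuple[MoleculeGraph, ConformerRecord]]
                   ) -> list[tuple[MoleculeGraph, list[ConformerRecord],
                                   MoleculeGraph, ConformerRecord]]:
    """Pair generated ensembles with references by record order, with a
    title cross-check warning when both sides carry titles."""
    if len(generated) != len(references):
        raise ValueError(
            f"record count mismatch: {len(generated)} generated vs "
            f"{len(references)} reference molecules")
    pairs = []
    for (gmol, ens), (rmol, rconf) in zip(generated, references):
        gt = gmol.title.split(" conf ")[0].strip()
        if gt and rmol.title and gt != rmol.title.strip():
            logger.warning("title mismatch in record pairing: %r vs %r",
                           gmol.title, rmol.title)
        pairs.append((gmol, ens, rmol, rconf))
    return pairs
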