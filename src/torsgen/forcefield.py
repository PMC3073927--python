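"""MMFF94 energy evaluation with the constant/variable term split.

Under torsion driving, bond lengths, bond angles and the out-of-plane
geometry never change, so the bond-stretch, angle-bend, stretch-bend and
out-of-plane MMFF94 terms are identical for every conformer of a
molecule.  Only torsion, van der Waals and electrostatic terms need to
be re-evaluated per conformer.  This module exposes that split as a
contract; the actual MMFF94 parameterisation and term evaluation are
delegated to RDKit's implementation behind :class:`FFContext`.

Energies are kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import ConformerRecord, MoleculeGraph

__all__ = ["FFContext", "ForcefieldError", "setup_forcefield",
           "variable_energy", "total_energy", "relax"]


class ForcefieldError(RuntimeError):
    """MMFF94 cannot parameterise the molecule."""


@dataclass
class FFContext:
    """Parameterised MMFF94 evaluators for one molecule.

    ``constant_terms`` (bond stretch + angle bend + stretch-bend +
    out-of-plane, evaluated once at the input geometry) plus the
    variable part reproduces the full MMFF94 energy for every
    torsion-driven conformer.
    """

    mol: MoleculeGraph = field(repr=False)
    constant_terms: float = 0.0
    _ff_total: object = field(default=None, repr=False)
    _ff_variable: object = field(default=None, repr=False)


def setup_forcefield(mol: MoleculeGraph, conf: ConformerRecord,
                     variant: str = "MMFF94") -> FFContext:
    """Parameterise MMFF94 for ``mol`` at the geometry of ``conf``.

    Raises :class:`ForcefieldError` for molecules the forcefield cannot
    type (these are rejected up front, before any search work).
    """
    rd = Chem.Mol(mol.rdmol)
    c = rd.GetConformer()
    for i in range(mol.n_atoms):
        c.SetAtomPosition(i, conf.coords[i].tolist())
    props_tot = AllChem.MMFFGetMoleculeProperties(rd, mmffVariant=variant)
    if props_tot is None:
        raise ForcefieldError(f"MMFF94 cannot handle molecule {mol.title!r}")
    ff_total = AllChem.MMFFGetMoleculeForceField(rd, props_tot)
    props_var = AllChem.MMFFGetMoleculeProperties(rd, mmffVariant=variant)
    props_var.SetMMFFBondTerm(False)
    props_var.SetMMFFAngleTerm(False)
    props_var.SetMMFFStretchBendTerm(False)
    props_var.SetMMFFOopTerm(False)
    ff_variable = AllChem.MMFFGetMoleculeForceField(rd, props_var)
    ctx = FFContext(mol=mol, _ff_total=ff_total, _ff_variable=ff_variable)
    pos = conf.coords.ravel().tolist()
    ctx.constant_terms = ff_total.CalcEnergy(pos) - ff_variable.CalcEnergy(pos)
    return ctx


def variable_energy(ctx: FFContext, conf: ConformerRecord) -> float:
    """Torsion + van der Waals + electrostatic energy at this geometry."""
    return float(ctx._ff_variable.CalcEnergy(conf.coords.ravel().tolist()))


def total_energy(ctx: FFContext, conf: ConformerRecord) -> float:
    """Full MMFF94 energy; equals constant_terms + variable_energy for
    torsion-driven conformers."""
    return float(ctx._ff_total.CalcEnergy(conf.coords.ravel().tolist()))


def relax(mol: MoleculeGraph, conf: ConformerRecord, steps: int = 200,
          variant: str = "MMFF94") -> ConformerRecord:
    """Optional input preparation: short MMFF94 minimisation (default 200
    iterations) of a single geometry.  Returns the relaxed record."""
    rd = Chem.Mol(mol.rdmol)
    c = rd.GetConformer()
    for i in range(mol.n_atoms):
        c.SetAtomPosition(i, conf.coords[i].tolist())
    props = AllChem.MMFFGetMoleculeProperties(rd, mmffVariant=variant)
    if props is None:
        raise ForcefieldError(f"MMFF94 cannot handle molecule {mol.title!r}")
    ff = AllChem.MMFFGetMoleculeForceField(rd, props)
    ff.Minimize(maxIts=steps)
    return ConformerRecord(rd.GetConformer().GetPositions().astype(float),
                           conf.rel_energy, conf.index)
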