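"""Embedded small-molecule fixtures.

Deterministic 3D SDF blocks for the molecules used throughout the test
suite and documentation: no generation at run time, no downloads.  The
geometries are synthetic idealized structures (exact hexagonal rings,
exact tetrahedral/three-fold groups) so that topological symmetries are
also exact geometric symmetries — see ``_fixture_data``.
"""

from __future__ import annotations

from ._fixture_data import MOLBLOCKS
from .chem import ConformerRecord, MoleculeGraph, molecules_from_sdf_text

__all__ = ["FIXTURE_NAMES", "make_fixture", "load_fixture"]

FIXTURE_NAMES = tuple(sorted(MOLBLOCKS))


def make_fixture(name: str) -> str:
    """The SDF text for a named fixture molecule."""
    try:
        block = MOLBLOCKS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    if not block.endswith("$$$$\n"):
        block = block.rstrip("\n") + "\n$$$$\n"
    return block


def load_fixture(name: str) -> tuple[MoleculeGraph, ConformerRecord]:
    """The perceived molecule + conformer for a named fixture."""
    return molecules_from_sdf_text(make_fixture(name))[0]
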