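"""On-the-fly RMSD diversity filtering.

Stored conformers live in a levelled "diversity tree": each level has a
radius, descending from 3.0 A down to the user's diversity cutoff d,
and sibling nodes at a level differ by at least that level's radius.
The first child of every parent holds the same conformer as the parent,
so descending a branch never re-computes an RMSD already known.

``fast_insert`` is the cheap filter used inside the generation loop: it
follows the first sufficiently-similar branch at each level, so it can
*falsely accept* a conformer that lands in a different branch from its
near-duplicate, but it never falsely rejects (every rejection has a
stored witness within d).  ``robust_prune`` is the exact energy-ordered
greedy filter applied afterwards with the symmetry-corrected RMSD; it
removes every leak the fast filter let through.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .chem import ConformerRecord

__all__ = ["DiversityTree", "TreeNode", "make_tree", "fast_insert", "robust_prune"]

TOP_RADIUS = 3.0
LADDER_FACTOR = 1.5

RmsdFn = Callable[[ConformerRecord, ConformerRecord], float]


@dataclass
class TreeNode:
    conf: ConformerRecord
    children: list["TreeNode"] = field(default_factory=list)


@dataclass
class DiversityTree:
    """Levelled diversity tree.

    ``level_radii`` is strictly decreasing and ends at the user cutoff d.
    ``roots`` are the siblings at the top level.  ``rmsd_evaluations``
    counts calls made through this tree (for accounting only).
    ``last_rejection`` records (candidate, stored witness, rmsd) for the
    most recent rejection.
    """

    level_radii: list[float]
    roots: list[TreeNode] = field(default_factory=list)
    rmsd_evaluations: int = 0
    n_stored: int = 0
    last_rejection: Optional[tuple[ConformerRecord, ConformerRecord, float]] = None

    @property
    def cutoff(self) -> float:
        return self.level_radii[-1]


def make_tree(d: float) -> DiversityTree:
    """Build an empty tree for diversity cutoff ``d``.

    Level radii descend from 3.0 A by a factor 1.5 (3.0, 2.0, 1.333, ...)
    truncated before the first value <= d, with d appended; if d >= 3.0
    the tree has the single level [d].
    """
    if d <= 0:
        raise ValueError("diversity cutoff must be positive")
    if d >= TOP_RADIUS:
        return DiversityTree(level_radii=[float(d)])
    radii = []
    r = TOP_RADIUS
    while r > d:
        radii.append(r)
        r /= LADDER_FACTOR
    radii.append(float(d))
    return DiversityTree(level_radii=radii)


def _new_chain(conf: ConformerRecord, levels_below: int) -> TreeNode:
    """A node for ``conf`` with the chain of single (self) children down
    to the bottom level."""
    node = TreeNode(conf=conf)
    cur = node
    for _ in range(levels_below):
        child = TreeNode(conf=conf)
        cur.children.append(child)
        cur = child
    return node


def fast_insert(tree: DiversityTree, conf: ConformerRecord, rmsd_fn: RmsdFn) -> bool:
    """Insert ``conf`` unless it is within the cutoff of a stored
    conformer reachable down the first similar branch.

    Returns True when the conformer was stored.  ``rmsd_fn`` should be
    the plain (non-symmetry-corrected) heavy-atom RMSD.
    """
    n_levels = len(tree.level_radii)
    siblings = tree.roots
    parent_rmsd: float | None = None  # rmsd to the conformer shared with parent
    for level in range(n_levels):
        radius = tree.level_radii[level]
        followed = None
        followed_rmsd = None
        for node in siblings:
            if parent_rmsd is not None and node is siblings[0]:
                # first child holds the parent's conformer: reuse the rmsd
                r = parent_rmsd
            else:
                r = rmsd_fn(conf, node.conf)
                tree.rmsd_evaluations += 1
            if r < radius:
                followed = node
                followed_rmsd = r
                break
        if followed is None:
            node = _new_chain(conf, n_levels - 1 - level)
            siblings.append(node)
            tree.n_stored += 1
            return True
        if level == n_levels - 1:
            tree.last_rejection = (conf, followed.conf, followed_rmsd)
            return False
        siblings = followed.children
        parent_rmsd = followed_rmsd
    raise AssertionError("unreachable")


def robust_prune(ensemble: list[ConformerRecord], d: float,
                 rmsd_fn_sym: RmsdFn) -> list[ConformerRecord]:
    """Exact energy-ordered greedy diversity filter.

    Conformers are visited in order of increasing ``rel_energy`` (ties
    broken by conformer index); one is kept iff its minimum
    symmetry-corrected RMSD to every previously kept conformer is >= d.
    The survivors therefore have all pairwise RMSDs >= d, and the result
    is independent of the order the ensemble was generated in.
    """
    if d <= 0:
        raise ValueError("diversity cutoff must be positive")
    kept: list[ConformerRecord] = []
    for conf in sorted(ensemble, key=lambda c: (c.rel_energy, c.index)):
        if all(rmsd_fn_sym(conf, k) >= d for k in kept):
            kept.append(conf)
    return kept
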