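# Methods

## Scope and model

`torsgen` generates conformers of a single molecule by *torsion
driving*: bond lengths, bond angles and ring geometries are taken from
the input structure and never changed; only dihedral angles about
rotatable bonds are set, each to values from a discrete allowed set.
The model therefore assumes the input 3D structure is reasonable
(e.g. a forcefield-optimised geometry) and that ring conformations are
already the ones of interest — ring sampling is out of scope, as is any
per-conformer re-minimisation (the optional `relax` helper exposes a
short MMFF94 minimisation for *input preparation* only).

A rotatable bond is an acyclic single bond whose two atoms each have at
least two non-hydrogen neighbours (the bond partner counts) and neither
of which is sp-hybridised.  This deliberately excludes
hydrogen-interchange rotations (methyl, hydroxyl): hydrogens are
excluded from every RMSD here, so those rotations cannot produce a
distinct conformer.

## Torsion library and symmetry folds

Allowed angles per bond come from a plain-text library: one rule per
line, `SMARTS angle angle ...`, `#` comments, exactly four atoms per
SMARTS with the middle two defining the bond, first match in file order
wins.  Bonds with no match fall back to 12 angles at 30° spacing.  The
bundled `data/torlib.txt` is this package's own, deliberately coarse
default (30° grids plus planar two-state rules for amide and ester
bonds); users with bond-specific angle preferences should supply their
own file via `--torlib`.

Topological symmetry then removes redundant grid points.  At each bond
end the *fold* is 2 for an sp² carbon whose two rotation-affected heavy
neighbours share a symmetry class, 3 for an sp³ carbon with three
same-class heavy neighbours, otherwise 1; end folds multiply and only
angles `< 360°/fold` survive.  Fold detection is restricted to carbon
ends and to heavy neighbours; an end whose rotation-affected neighbours
are hydrogens gets no fold (such bonds are usually not rotors at all).
Symmetry classes are an iterative-refinement (Morgan-style) partition
of the heavy-atom graph seeded with (element, heavy degree, formal
charge, ring membership, sorted heavy-bond orders) and refined with
neighbour-class multisets to a fixed point; class ids are ranks of the
refinement keys and hence invariant under atom relabelling.  The seed
invariants are this package's choice; they are sufficient for the
2-/3-fold detection the fold rules need.

Because the energies of fold-equivalent torsions are equal only up to
the *geometric* accuracy of the input's local symmetry, the test
fixtures are built from exact internal coordinates (regular hexagons,
exact three-fold tert-butyl groups); with them the 6-fold degeneracy on
tert-butylbenzene holds to ~2 × 10⁻⁴ kcal/mol.  On relaxed real-world
geometries the degeneracy is only approximate, which is harmless: fold
reduction is applied before any energy is computed.

## Energies

All energies are MMFF94 (RDKit's implementation; kcal/mol).  The term
split — constant (bond stretch, angle bend, stretch-bend, out-of-plane)
versus variable (torsion, van der Waals, electrostatic) — is exact
under torsion driving and is verified to 10⁻⁶ kcal/mol in the tests.
Electrostatics use the adapter's MMFF94 defaults (distance-dependent
dielectric as implemented there).  The MMFF94s variant can be selected
through the adapter (`setup_forcefield(..., variant="MMFF94s")`);
plain MMFF94 is the default.  Molecules the forcefield cannot type are
rejected up front; the CLI logs and skips them.

The greedy seed estimates the global grid minimum: rotors are ordered
by centrality (eccentricity of the bond's nearer atom on the heavy-atom
graph, most central first, ties by input bond order); one outward pass
sets each rotor to its variable-energy argmin with the others fixed,
starting from the input geometry; the pass is repeated for up to 16
lexicographically-first orderings of the ≤ 4 most central rotors (all
`k!` orderings when fewer).  Per-rotor argmins use the variable energy
— equivalent to total energy up to the constant offset.  The best total
energy found becomes the initial energy-window reference; during
enumeration the reference drops whenever a lower energy appears, and
the final window is re-applied against the final reference so the
output window is exact.

## Enumeration

The torsion grid is a mixed-radix index space (rotor 0, most central,
least significant).  Indices are visited in the order of a
maximal-length Galois LFSR: the smallest width `k` with `2^k − 1 ≥ n`
is chosen, one published primitive-polynomial tap mask per width 2–32
is hard-coded (each width's full period is unit-tested exhaustively up
to 2¹⁷), emitted values above `n` are skipped, and the caller maps
`v → v − 1`.  The traversal is deterministic — two runs are
bit-identical — and covers each index exactly once, so the conformer
cap (default 10⁶) truncates without bias toward the input conformation.

## Diversity filtering

Two filters with different contracts:

* **Fast filter** (inside the loop): a levelled diversity tree with
  radii descending from 3.0 Å by factor 1.5 and ending at the user
  cutoff `d` (so `d = 1.6` gives 3.0/2.0/1.6 — the ladder rule is this
  package's choice).  Insertion follows the *first* sibling within the
  level radius downward, reusing the parent's RMSD for the self-child,
  and rejects only at the bottom level.  It never falsely rejects
  (every rejection has a stored witness within `d`, recorded on the
  tree) but may falsely accept across branches.  It uses the plain
  heavy-atom RMSD (Kabsch superposition, proper rotations only —
  mirror images are distinct conformers).
* **Exact prune** (afterwards): conformers sorted by (relative energy,
  index); one is kept iff its minimum *symmetry-corrected* RMSD to all
  previously kept ones is ≥ `d`.  The symmetry correction minimises
  over the heavy-atom graph automorphisms (networkx enumeration, capped
  at 5000; past the cap the correction degrades to identity with a
  warning), eliminating spurious differences between conformations that
  merely permute topologically equivalent atoms.

A design point where this package is deliberately stricter than a pure
streaming filter: the search loop records the `(index, energy)` pair of
*every* conformer that passes the provisional energy window — scalars,
so memory stays small even for millions of grid points — and the final
prune runs over all of them, rebuilding discarded geometries by index.
A prune restricted to the fast filter's survivors can lose conformers
whose rejection witness is itself later pruned, making the output
depend on traversal order; pruning the full window makes the ensemble
exactly the greedy optimum over all low-energy grid conformers and
provably independent of the LFSR order (verified against a brute-force
reference pipeline on every fixture).  The trade-off is a second
geometry build plus `O(n_window × n_kept)` RMSDs in the worst case;
the energy-sorted scan short-circuits on the first violation, which in
practice keeps this far below the full pairwise cost.

Ties in the prune ordering are broken by conformer index.  Degenerate
inputs: zero-rotor molecules return the input conformer alone; an
all-zero-coordinate input is rejected as not 3D; collinear torsion
reference frames raise an error.

## Evaluation

`calcrmsd` pairs generated ensembles with reference structures by
record order (title mismatches warn; heavy-graph mismatches are
errors), computes each molecule's minimum symmetry-corrected RMSD, and
reports percent recovery — `100 × |{min RMSD ≤ c}| / N` — at 1.0, 1.5
and 2.0 Å, plus per-rotor-count medians of conformer counts and minimum
RMSD (pandas).  When a reference's torsions all lie on grid points the
diversity level bounds its minimum RMSD (the grid point is generated,
and if pruned it was within `d` of a kept conformer); this is asserted
on constructed cases in the tests.

## What the fixtures do and do not show

The embedded fixtures are small (1–2 rotors, ≤ 24 atoms) idealized
geometries chosen to make symmetry properties exact and every
brute-force oracle affordable; the recovery smoke test runs the full
generate-and-evaluate pipeline on them at `d = 1.5 Å` with the input
geometry as reference.  Passing these tests demonstrates the
correctness of the machinery — grid construction, fold reduction,
enumeration coverage, window and diversity contracts, symmetry-corrected
recovery — not the recovery statistics achievable on real crystal-
structure benchmarks, which depend on the torsion library's angle sets,
the forcefield build, and molecules far larger than the fixtures.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `diversity_d` | required | minimum pairwise heavy-atom RMSD (Å) |
| `energy_cutoff` | 50 kcal/mol | window above the lowest-energy conformer |
| `conformer_cap` | 10⁶ | maximum grid conformers tested |
| fallback grid | 12 × 30° | bonds without a library match |
| tree top radius | 3.0 Å | first diversity-tree level |
| ladder factor | 1.5 | ratio between successive tree radii |
| automorphism cap | 5000 | symmetry-correction enumeration limit |
| relax steps | 200 | optional input-preparation minimisation |
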