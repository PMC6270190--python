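# Methods

## The model

`templink` treats a two-pocket inhibitor as three covalently joined parts:
two pocket-binding fragments and a linker. The working assumption —
inherited from fragment-based design practice — is that each fragment's
contribution to binding is approximately additive and can be estimated by
docking the fragment alone into its pocket. The per-fragment quality
metric is **group efficiency**,

GE = −E_dock / N_heavy,

the docking energy (kcal/mol) divided by the number of non-hydrogen atoms.
Dividing by size penalizes bloated fragments: a fragment that gains
affinity only by adding atoms does not gain GE. Stored GE is positive for
binders (negative energies); values are displayed rounded to two decimals
half-away-from-zero, but every comparison uses the unrounded number.

Selection is *template-relative*: a library pose in region r survives iff

GE(pose) ≥ GE(template fragment r) and E(pose) ≤ E(template fragment r),

both inclusive. Inclusivity is load-bearing: it guarantees the template's
own fragments survive, so the template is always regenerated and — having
the weakest admissible fragment pair — ranks last among survivors. That
closure is the pipeline's internal control and is asserted in the tests.

Candidates are ranked by the sum of the two fragment GE scores. The GE sum
of a candidate is computed from its fragments' docked energies, not from
re-docking the assembled molecule; no binding-energy re-estimation
(force-field minimization, MD, LIE) is performed.

## Geometry of linker splicing

Attachment points are monovalent placeholder (dummy) atoms bonded to one
heavy anchor. For a linker with points (p1, p2) and pocket poses with
attachment sites a1, a2:

1. translate the linker rigidly so p1's placeholder coincides with a1;
2. form vector1 = a1→a2 and vector2 = p1→p2 and rotate the linker about
   a1 by the Rodrigues rotation taking vector2's direction onto vector1's;
3. the residual gap is |rotated p2 − a2|; the placement is accepted iff
   gap < 0.1 Å (strict, configurable).

Since the rotation aligns directions exactly, the gap equals
| |vector1| − |vector2| | — a closed form the implementation is checked
against to 1e−6 Å. Degenerate cases: zero-length vectors reject the
placement with a reason; the antiparallel case (rotation axis undefined)
rotates 180° about a deterministic perpendicular axis (the smallest-index
coordinate axis not parallel to vector1, orthogonalized), keeping runs
reproducible. All attachment-point pairs are tried as *ordered* pairs
(point1 always faces pocket 1), matching the asymmetric construction.

Unannotated building blocks (no placeholder) bond at the heavy atom
nearest the relevant linker anchor after a centroid pre-alignment, ties
broken by lowest atom index; one explicit hydrogen on that atom (the one
best aligned with the new bond) is removed if present. Bond formation
deletes the used placeholders and adds single anchor–anchor bonds; unused
attachment placeholders are capped as hydrogens at the placeholder
position. Merged candidates are valence-checked (RDKit sanitization);
failures are discarded with a logged reason. Duplicate candidates (same
canonical SMILES) are merged keeping all provenances and the maximum GE
sum — the optimistic reading, since provenances differ only in pose
geometry, not topology. No post-assembly geometry relaxation is done; the
junction bond lengths follow from placing anchors at placeholder
positions (placeholders sit where the former partner atom was, so
template reassembly is exact).

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| `box_edge` | 10 Å | cubic search-region edge, centered on each template fragment's geometric center ("10 Å grid box" read as 10 Å per side, the docking-program convention) |
| `max_poses` | 8 | docked poses kept per block per region (ascending energy) |
| `gap_threshold` | 0.1 Å | strict upper bound on the splice gap; raise to admit more linkers |
| `energy_window` | off | optional per-block window above the best mode; the pose-retention rule is ambiguous in the source protocol, so the window defaults to keeping everything up to `max_poses` |
| `mw_max` | 550 g/mol | the modified Rule-of-Five weight bound (classic bounds otherwise) |
| `max_violations` | 0 | 0 = every rule must pass (removal-filter reading); 1 = Lipinski's classic "at most one violation" |
| box overhang tolerance | 2 Å | imported poses whose center leaves the region box by more than this are dropped |

Units are Å for coordinates, kcal/mol for energies, g/mol for masses
throughout.

Descriptors use the classic Rule-of-Five definitions: donors = N/O atoms
bearing ≥1 H, acceptors = N/O count, logP = Wildman–Crippen atom
contributions. Note that Crippen logP rates sorafenib at 5.55, so under
the strict all-rules mode the template itself would be removed in Step 4;
the reassembly-closure fixtures therefore run with `max_violations=1`,
the reading consistent with the template surviving its own pipeline.
The unstable-substructure blacklist (peroxide, contiguous N–N–N,
heteroatom–halogen, orthoester, aminal, hemiacetal, acyl halide, geminal
diol) is a configurable default: the protocol calls for removing
synthetically improbable bonds without enumerating them, so the list is a
design choice of this package.

Ranking ties are broken by ascending molecular weight, then lexicographic
canonical SMILES, making the output a total order independent of input
permutation.

## Synthetic data

`generate_synthetic_library(n_blocks, n_linkers, seed)` draws building
blocks from a fixed pool of common medicinal-chemistry fragments (azines,
azoles, anilines, saturated N/O heterocycles, simple benzamides) with
seeded ETKDG 3D embedding, and linkers from pools with 2, 3 or 4
attachment points mixed 0.2/0.6/0.2 — averaging three bonding locations
per linker, the composition of typical linker collections. When a template
decomposition is supplied, the template's own pieces are appended so the
library can always reassemble it. `mock_dock` provides deterministic
rigid-body placements inside a region box with the documented toy energy
E = −0.5 · N_heavy · (1 − d/edge), d being the placement center's offset
from the box center: reproducible, ordered, always negative inside the
box.

What the synthetic path emulates: library composition, pose multiplicity,
energy ordering, spatial containment, and the combinatorial structure of
the sweep. What it does not emulate: real docking energetics, pose
clustering/diversity, receptor shape, or protonation effects — so green
tests demonstrate the correctness of the scoring, geometry, filtering and
ranking machinery, not the virtual-screening performance of any docking
engine. Library-scale candidate counts obtained with a real docking
program are correspondingly out of scope.

Test and demonstration runs use desk-scale problem sizes (tens of blocks,
a handful of linkers, 8 poses each), which exercise every code path in
seconds; all sizes scale by configuration only.

## Numerical choices and limitations

- Rotations are built explicitly (Rodrigues); every matrix is validated in
  tests as proper (det = +1) and orthogonal to 1e−9, and placements are
  rigid to 1e−6 Å in pairwise distances.
- Template cuts are restricted to acyclic single bonds; cutting must yield
  exactly three connected pieces. Ring cuts are rejected (chemically
  meaningless for this construction).
- SMILES inputs are embedded with seeded ETKDGv3; molecules containing
  dummy atoms are embedded with the dummies temporarily treated as carbon
  (the distance-bounds builder cannot handle zero-mass atoms), which also
  gives the placeholder a realistic partner-atom bond length. A
  random-coordinate fallback covers pathological cases.
- PDBQT import maps model coordinates onto a reference library block by
  heavy-atom order (the format carries no bond graph); SDF import needs no
  reference but can verify pose graphs against a library when given one.
- Linkers with three or more attachment points are used pairwise only;
  bonding a third fragment is not supported.
- GE additivity is an approximation: cooperative or clashing
  fragment–fragment interactions across the linker are invisible to the
  score.
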